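import numpy as np
import pytest

from _oracles import brute_orfs
from salmotx.coding import (
    MotifDomainScanner,
    Orf,
    _pick_cutoff,
    annotate_domains,
    categorize_loci,
    find_orfs,
    klet_shuffle,
    kmer_counts,
    score_transcripts,
    train_codpot,
)


def _random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


NON_STOP = [c for c in
            (a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT")
            if c not in {"TAA", "TAG", "TGA"}]


def _coding_seq(rng, n_codons=120):
    body = "ATG" + "".join(
        NON_STOP[i] for i in rng.integers(0, len(NON_STOP), size=n_codons - 1)
    )
    return body + "TAA"


class TestFindOrfs:
    def test_no_atg_gives_no_orf(self):
        assert find_orfs("CCCCCCGGGGGGTTTCCC", min_aa=1) == []

    def test_constructed_100aa_orf(self, rng):
        seq = _coding_seq(rng, n_codons=100)  # ATG + 99 codons + stop
        orfs = find_orfs(seq, min_aa=100)
        assert len(orfs) == 1
        assert orfs[0].length_aa == 100
        assert orfs[0].peptide.startswith("M")
        assert orfs[0].complete

    def test_min_aa_boundary_is_inclusive(self, rng):
        seq = _coding_seq(rng, n_codons=100)
        assert len(find_orfs(seq, min_aa=100)) == 1
        assert find_orfs(seq, min_aa=101) == []

    def test_three_prime_partial_allowed(self):
        seq = "ATG" + "GCT" * 120  # no stop: runs off the end
        orfs = find_orfs(seq, min_aa=100)
        assert len(orfs) == 1
        assert not orfs[0].complete
        assert orfs[0].length_aa == 121

    def test_n_codon_breaks_orf(self):
        seq = "ATG" + "GCT" * 50 + "GNT" + "GCT" * 60 + "TAA"
        assert find_orfs(seq, min_aa=100) == []
        # but the run after the N can host its own ORF
        seq2 = "ATG" + "GCT" * 10 + "GNT" + "ATG" + "GCT" * 110 + "TAA"
        orfs = find_orfs(seq2, min_aa=100)
        assert len(orfs) == 1 and orfs[0].length_aa == 111

    def test_empty_sequence(self):
        assert find_orfs("", min_aa=1) == []

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError):
            find_orfs("ATGXXX", min_aa=1)

    def test_agrees_with_brute_force_three_frame_scan(self, rng):
        for _ in range(300):
            n = int(rng.integers(10, 400))
            seq = _random_seq(rng, n)
            if rng.random() < 0.3:  # sprinkle Ns
                pos = rng.integers(0, n, size=max(1, n // 50))
                seq = "".join(
                    "N" if i in set(pos.tolist()) else ch
                    for i, ch in enumerate(seq)
                )
            got = {
                (o.frame, (o.start - 1 - o.frame) // 3, o.length_aa)
                for o in find_orfs(seq, min_aa=5)
            }
            expected = set(brute_orfs(seq, min_aa=5))
            assert got == expected, seq


class TestKletShuffle:
    def test_homopolymer_unchanged(self):
        assert klet_shuffle("AAAAAA", k=2, seed=0) == "AAAAAA"

    def test_short_sequence_returned_unchanged(self):
        assert klet_shuffle("ACGTA", k=7, seed=0) == "ACGTA"

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError):
            klet_shuffle("ACGU", k=2, seed=0)

    @pytest.mark.parametrize("k", [1, 2, 3, 7])
    def test_kmer_multiset_preserved(self, rng, k):
        for trial in range(25):
            seq = _random_seq(rng, int(rng.integers(max(k + 1, 20), 800)))
            out = klet_shuffle(seq, k=k, seed=int(rng.integers(2**31)))
            assert len(out) == len(seq)
            assert kmer_counts(out, k) == kmer_counts(seq, k)

    def test_lower_order_counts_also_preserved(self, rng):
        seq = _random_seq(rng, 1000)
        out = klet_shuffle(seq, k=7, seed=1)
        for k in (1, 2, 6):
            assert kmer_counts(out, k) == kmer_counts(seq, k)

    def test_shuffles_vary_with_seed(self, rng):
        seq = _random_seq(rng, 500)
        assert klet_shuffle(seq, k=2, seed=1) != klet_shuffle(seq, k=2, seed=2)

    def test_same_seed_is_deterministic(self, rng):
        seq = _random_seq(rng, 500)
        assert klet_shuffle(seq, k=3, seed=9) == klet_shuffle(seq, k=3, seed=9)


class TestCutoffSelection:
    def test_symmetric_scores_give_half(self):
        scores = np.array([0.1, 0.4, 0.6, 0.9])
        labels = np.array([0, 0, 1, 1])
        assert _pick_cutoff(scores, labels) == pytest.approx(0.5)

    def test_equals_brute_force_threshold_scan(self, rng):
        for _ in range(50):
            scores = rng.random(40)
            labels = rng.integers(0, 2, size=40)
            if labels.sum() in (0, 40):
                continue
            got = _pick_cutoff(scores, labels)
            uniq = np.unique(scores)
            cands = np.sort(np.concatenate([uniq, (uniq[:-1] + uniq[1:]) / 2]))
            best = None
            for c in cands:
                sens = ((scores >= c) & (labels == 1)).sum() / (labels == 1).sum()
                spec = ((scores < c) & (labels == 0)).sum() / (labels == 0).sum()
                j = sens + spec
                if best is None or j > best[0] + 1e-12:
                    best = (j, c)
            assert got == pytest.approx(best[1])

    def test_invariant_to_score_order(self, rng):
        scores = rng.random(60)
        labels = rng.integers(0, 2, size=60)
        labels[:5] = 1
        labels[5:10] = 0
        perm = rng.permutation(60)
        assert _pick_cutoff(scores, labels) == _pick_cutoff(scores[perm], labels[perm])


@pytest.fixture(scope="module")
def trained():
    rng = np.random.default_rng(11)
    # biased codon usage so hexamer features generalize
    w = np.exp(-np.arange(len(NON_STOP)) / 10.0)
    w /= w.sum()

    def coding(n_codons):
        idx = rng.choice(len(NON_STOP), size=n_codons, p=w)
        return ("ATG" + "".join(NON_STOP[i] for i in idx) + "TAA"
                + "".join("ACGT"[i] for i in rng.integers(0, 4, 60)))

    mrnas = [coding(int(rng.integers(110, 180))) for _ in range(40)]
    model, report = train_codpot(mrnas, seed=5)
    return mrnas, model, report


class TestCodpotTraining:
    def test_separable_training_has_perfect_cv(self, trained):
        _, _, report = trained
        assert report.folds == 10
        assert np.mean(report.fold_sensitivity) >= 0.95
        assert np.mean(report.fold_specificity) >= 0.95

    def test_training_mrnas_score_above_cutoff(self, trained):
        mrnas, model, _ = trained
        results = score_transcripts(model, {f"m{i}": s for i, s in enumerate(mrnas)})
        frac = np.mean([r.label == "coding" for r in results])
        assert frac >= 0.95

    def test_shuffled_candidates_score_below_cutoff(self, trained):
        mrnas, model, _ = trained
        shuffled = {
            f"s{i}": klet_shuffle(s, k=7, seed=i) for i, s in enumerate(mrnas)
        }
        results = score_transcripts(model, shuffled)
        frac = np.mean([r.label == "noncoding" for r in results])
        assert frac >= 0.95

    def test_empty_candidate_list(self, trained):
        _, model, _ = trained
        assert score_transcripts(model, {}) == []

    def test_small_training_set_rejected(self):
        with pytest.raises(ValueError, match="at least 20"):
            train_codpot(["ATGGCTTAA"] * 10)

    def test_degenerate_training_set_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            train_codpot(["ATGGCTTAA" * 40] * 25)


class TestDomainsAndCategories:
    def test_motif_scanner_detects_planted_motif(self):
        scanner = MotifDomainScanner(["TGGCATGAGGAT"])
        assert scanner.has_domain("AAA" + "TGGCATGAGGAT" + "CCC")
        assert not scanner.has_domain("AAATTTCCCGGG")

    def test_annotate_domains_scans_orf_span(self):
        seq = "ATG" + "TGGCATGAGGAT" + "GCT" * 20 + "TAA"
        orfs = {"t1": find_orfs(seq, min_aa=10, transcript_id="t1")}
        annotate_domains(orfs, {"t1": seq}, MotifDomainScanner(["TGGCATGAGGAT"]))
        assert orfs["t1"][0].domain_hit

    @pytest.fixture
    def category_setup(self):
        from salmotx.annotation import Exon, GenomeAnnotation, Locus, Transcript
        from salmotx.coding import CodingPotentialResult
        from salmotx.compare import TranscriptComparison as TC

        def locus(lid, tids, length=300):
            ts = [
                Transcript(tid, "c1", "+", [Exon("c1", 1 + i * 1000,
                                                 i * 1000 + length)])
                for i, tid in enumerate(tids)
            ]
            return Locus(lid, "c1", "+", ts)

        reference = GenomeAnnotation([])
        return locus, reference, TC, CodingPotentialResult

    def test_all_u_locus_with_gated_orf_is_new_coding(self, category_setup):
        locus, reference, TC, CPR = category_setup
        ann_locus = locus("L1", ["t1"])
        from salmotx.annotation import GenomeAnnotation

        orf = Orf("t1", 0, 1, 453, 150, "M" * 150, domain_hit=True)
        cats = categorize_loci(
            GenomeAnnotation([ann_locus]),
            {"t1": TC("t1", "u")},
            {"t1": [orf]},
            [CPR("t1", 0.9, (300, 450, 0.5, 1.0), "coding")],
            reference,
        )
        assert cats[0].category == "new_coding"

    def test_all_u_noncoding_long_enough_is_lincRNA(self, category_setup):
        locus, reference, TC, CPR = category_setup
        from salmotx.annotation import GenomeAnnotation

        cats = categorize_loci(
            GenomeAnnotation([locus("L1", ["t1"], length=300)]),
            {"t1": TC("t1", "u")},
            {"t1": []},
            [CPR("t1", 0.1, (300, 0, 0.0, 0.0), "noncoding")],
            reference,
        )
        assert cats[0].category == "lincRNA"

    def test_short_noncoding_u_locus_is_excluded(self, category_setup):
        locus, reference, TC, CPR = category_setup
        from salmotx.annotation import GenomeAnnotation

        cats = categorize_loci(
            GenomeAnnotation([locus("L1", ["t1"], length=150)]),
            {"t1": TC("t1", "u")},
            {"t1": []},
            [CPR("t1", 0.1, (150, 0, 0.0, 0.0), "noncoding")],
            reference,
        )
        assert cats[0].category == "excluded"

    def test_mixed_u_and_j_locus_is_not_a_new_category(self, category_setup):
        locus, reference, TC, CPR = category_setup
        from salmotx.annotation import GenomeAnnotation

        cats = categorize_loci(
            GenomeAnnotation([locus("L1", ["t1", "t2"])]),
            {"t1": TC("t1", "u"), "t2": TC("t2", "j", "refX")},
            {"t1": [], "t2": []},
            [CPR("t1", 0.1, (300, 0, 0, 0), "noncoding"),
             CPR("t2", 0.1, (300, 0, 0, 0), "noncoding")],
            reference,
        )
        assert cats[0].category not in {"new_coding", "lincRNA"}

    def test_planted_categories_recovered(self, default_study):
        res = default_study
        truth_cats = {
            lid: cat for lid, cat in res.truth.category_of.items()
            if cat in {"new_coding", "lincRNA"}
        }
        hits = sum(
            1 for lid, cat in truth_cats.items() if res.categories.get(lid) == cat
        )
        assert hits / len(truth_cats) >= 0.95
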