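import numpy as np
import pandas as pd
import pytest

from _oracles import brute_bh, brute_tau
from salmotx import expression as ex
from salmotx.annotation import SampleTable


def _counts(rows, samples=None):
    arr = np.asarray(rows)
    return pd.DataFrame(
        arr,
        index=[f"L{i}" for i in range(arr.shape[0])],
        columns=samples or [f"s{j}" for j in range(arr.shape[1])],
    )


def _two_group_samples(n=12, tissues=("ovary", "pituitary")):
    return SampleTable(
        {f"{t}_{i}": t for t in tissues for i in range(n)}
    )


class TestFilterLow:
    def test_boundary_just_above_three_kept(self):
        counts = _counts([[4, 4] + [0] * 10])
        assert len(ex.filter_low(counts)) == 1

    def test_exactly_three_everywhere_removed(self):
        counts = _counts([[3] * 12])
        assert len(ex.filter_low(counts)) == 0

    def test_all_zero_removed(self):
        counts = _counts([[0] * 12])
        assert len(ex.filter_low(counts)) == 0

    def test_single_high_sample_not_enough(self):
        counts = _counts([[100] + [0] * 11])
        assert len(ex.filter_low(counts)) == 0


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = _counts([[10, 10, 10], [50, 50, 50], [7, 7, 7]])
        assert np.allclose(ex.size_factors(counts), 1.0)

    def test_doubled_sample_has_double_factor(self, rng):
        base = rng.integers(5, 200, size=(50, 4))
        counts = _counts(np.column_stack([base, 2 * base[:, 0]]))
        f = ex.size_factors(counts)
        assert f.iloc[4] / f.iloc[0] == pytest.approx(2.0)

    def test_two_by_two_hand_example(self):
        counts = _counts([[10, 20], [10, 20]])
        f = ex.size_factors(counts)
        # reference = geometric mean sqrt(200); median ratios 10/sqrt(200),
        # 20/sqrt(200): factors proportional to (1, 2)
        assert f.iloc[1] / f.iloc[0] == pytest.approx(2.0)
        assert np.prod(f.values) == pytest.approx(1.0)

    def test_zero_containing_loci_need_prefilter(self):
        counts = _counts([[0, 10], [10, 0]])
        with pytest.raises(ValueError, match="filter"):
            ex.size_factors(counts)


class TestVst:
    def test_zero_count_maps_to_zero(self):
        counts = _counts([[0, 4]])
        factors = pd.Series([1.0, 1.0], index=counts.columns)
        assert ex.vst(counts, factors).iloc[0, 0] == 0.0

    def test_count_equal_to_factor_maps_to_one(self):
        counts = _counts([[2, 4]])
        factors = pd.Series([2.0, 1.0], index=counts.columns)
        assert ex.vst(counts, factors).iloc[0, 0] == 1.0

    def test_scaling_counts_and_factor_together_is_identity(self, rng):
        base = rng.integers(1, 100, size=(20, 3))
        counts = _counts(base)
        factors = pd.Series([1.0, 1.0, 1.0], index=counts.columns)
        doubled = counts.copy()
        doubled["s1"] *= 2
        factors2 = factors.copy()
        factors2["s1"] = 2.0
        assert np.allclose(ex.vst(counts, factors), ex.vst(doubled, factors2))


class TestTpmAndTau:
    def test_tpm_columns_sum_to_a_million(self, rng):
        counts = _counts(rng.integers(0, 500, size=(200, 6)))
        lengths = pd.Series(rng.integers(200, 5000, size=200), index=counts.index)
        t = ex.tpm(counts, lengths)
        assert np.allclose(t.sum(axis=0), 1e6, atol=1e-3)

    def test_single_tissue_expression_gives_tau_one(self):
        samples = SampleTable(
            {f"{t}_{i}": t
             for t in ("immature_testis", "mature_testis", "ovary", "pituitary")
             for i in range(2)}
        )
        counts = pd.DataFrame(
            [[4000, 4000, 0, 0, 0, 0, 0, 0],
             [10**6] * 8],
            index=["specific", "background"], columns=samples.samples,
        )
        lengths = pd.Series([1000, 1000], index=counts.index)
        table = ex.tau_profiles(counts, lengths, samples)
        assert table.loc["specific", "tau"] == pytest.approx(1.0)

    def test_uniform_expression_gives_tau_zero(self):
        samples = SampleTable(
            {f"{t}_{i}": t
             for t in ("immature_testis", "mature_testis", "ovary", "pituitary")
             for i in range(2)}
        )
        # identical columns: TPM profiles equal in every tissue
        counts = pd.DataFrame(
            [[100] * 8, [50] * 8], index=["a", "b"], columns=samples.samples
        )
        lengths = pd.Series([1000, 500], index=counts.index)
        table = ex.tau_profiles(counts, lengths, samples)
        assert np.allclose(table["tau"], 0.0, atol=1e-9)

    def test_printed_formula_direct_evaluation(self):
        # xhat = (1, 1/3, 1/3, 1/3) -> tau = (0 + 3*(2/3)) / 3 = 2/3
        assert brute_tau([3.0, 1.0, 1.0, 1.0]) == pytest.approx(2.0 / 3.0)

    def test_tau_agrees_with_brute_force_on_random_profiles(self, rng):
        samples = SampleTable(
            {f"{t}_{i}": t
             for t in ("immature_testis", "mature_testis", "ovary", "pituitary")
             for i in range(3)}
        )
        counts = _counts(
            rng.integers(0, 2000, size=(500, 12)), samples=samples.samples
        )
        lengths = pd.Series(
            rng.integers(300, 3000, size=500), index=counts.index
        )
        table = ex.tau_profiles(counts, lengths, samples)
        # naive recomputation: TPM -> floor/log2 -> tissue means -> formula
        t = counts.div(lengths, axis=0)
        t = t.div(t.sum(axis=0), axis=1) * 1e6
        for locus in table.index:
            x = []
            for tissue in samples.tissues:
                vals = [
                    (np.log2(t.loc[locus, s]) if t.loc[locus, s] >= 1 else 0.0)
                    for s in samples.samples_of(tissue)
                ]
                x.append(float(np.mean(vals)))
            assert table.loc[locus, "tau"] == pytest.approx(brute_tau(x))

    def test_tau_requires_two_tissues(self):
        counts = _counts([[1, 2]])
        with pytest.raises(ValueError):
            samples = SampleTable({"s0": "ovary", "s1": "ovary"})

    def test_tau_invariant_to_scaling_one_locus(self):
        # multiplying all of one locus's tissue means by a constant leaves
        # tau unchanged (max-normalization)
        x = [8.0, 2.0, 1.0, 0.0]
        assert brute_tau(x) == pytest.approx(brute_tau([3 * v for v in x]))


class TestPairwiseDe:
    def test_identical_group_means_give_zero_log2fc(self):
        samples = _two_group_samples(3)
        counts = _counts(
            [[10] * 6, [200] * 6], samples=samples.samples
        )
        res = ex.pairwise_de(counts, samples, ("ovary", "pituitary"))
        assert np.allclose(res.table["log2fc"], 0.0)

    def test_power_at_planted_eightfold_change(self, rng):
        """Planted 2^3 fold change, 12 vs 12, NB dispersion 0.05: the locus
        passes log2FC >= 2 and padj <= 0.01 in >= 90% of replicates."""
        samples = _two_group_samples(12)
        n_null, n_rep, hits = 100, 200, 0
        for _ in range(n_rep):
            base = np.exp(rng.normal(np.log(100), 1.0, size=n_null + 1))
            mu = np.tile(base[:, None], (1, 24))
            mu[0, :12] *= 8.0  # planted, upregulated in ovary
            r = 1 / 0.05
            counts = _counts(
                rng.negative_binomial(r, r / (r + mu)), samples=samples.samples
            )
            res = ex.pairwise_de(counts, samples, ("ovary", "pituitary"))
            row = res.table.iloc[0]
            if row["log2fc"] >= 2.0 and row["padj"] <= 0.01:
                hits += 1
        assert hits / n_rep >= 0.90

    def test_null_simulation_controls_false_calls(self, rng):
        samples = _two_group_samples(12)
        n = 2000
        base = np.exp(rng.normal(np.log(100), 1.0, size=n))
        r = 1 / 0.05
        mu = np.tile(base[:, None], (1, 24))
        counts = _counts(
            rng.negative_binomial(r, r / (r + mu)), samples=samples.samples
        )
        res = ex.pairwise_de(counts, samples, ("ovary", "pituitary"))
        called = (
            (res.table["log2fc"].abs() >= 2.0) & (res.table["padj"] <= 0.01)
        ).mean()
        se = np.sqrt(0.01 * 0.99 / n)
        assert called <= 0.01 + 3 * se

    def test_too_few_samples_rejected(self):
        samples = SampleTable({"a": "ovary", "b": "pituitary", "c": "pituitary"})
        counts = _counts([[5, 5, 5]], samples=["a", "b", "c"])
        with pytest.raises(ValueError, match=">=2 samples"):
            ex.pairwise_de(counts, samples, ("ovary", "pituitary"))

    def test_adjusted_p_monotone_and_bh_matches_oracle(self, rng):
        p = rng.random(200)
        from statsmodels.stats.multitest import multipletests

        adj = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(adj, brute_bh(list(p)))
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all()


class TestSingleTissueCalls:
    def test_rule_application_on_study(self, default_study):
        res = default_study
        up = res.tissue_specific["upregulated_single_tissue"]
        planted = {
            l: t for l, t in res.truth.tissue_specific_of.items() if t is not None
        }
        recovered = sum(
            1 for l, t in planted.items() if l in up.index and up[l] == t
        )
        assert recovered / len(planted) >= 0.9

    def test_tau_threshold_is_strict(self):
        up = pd.Series(["ovary", "ovary", None], index=["a", "b", "c"])
        tau = pd.DataFrame({"tau": [0.9, 0.8, 1.0]}, index=["a", "b", "c"])
        calls = ex.call_tissue_specific(up, tau)
        assert bool(calls.loc["a", "tissue_specific"])
        assert not bool(calls.loc["b", "tissue_specific"])  # tau == 0.8
        assert not bool(calls.loc["c", "tissue_specific"])  # not upregulated

    def test_full_tissue_specific_recovery(self, default_study):
        res = default_study
        planted = {
            l: t for l, t in res.truth.tissue_specific_of.items() if t is not None
        }
        ts = res.tissue_specific
        ok = sum(
            1
            for l, t in planted.items()
            if l in ts.index
            and bool(ts.loc[l, "tissue_specific"])
            and ts.loc[l, "upregulated_single_tissue"] == t
        )
        assert ok / len(planted) >= 0.9

    def test_background_loci_rarely_called(self, default_study):
        res = default_study
        truth = res.truth
        ts = res.tissue_specific
        background = [
            l for l in ts.index
            if truth.tissue_specific_of.get(l) is None
            and truth.module_of.get(l) is None
        ]
        fp = sum(bool(ts.loc[l, "tissue_specific"]) for l in background)
        assert fp / len(background) <= 0.01


class TestQcPca:
    def test_planted_clusters_separate_on_pcs(self, default_study):
        from sklearn.metrics import silhouette_score

        res = default_study
        factors = ex.size_factors(res.filtered_counts)
        v = ex.vst(res.filtered_counts, factors)
        pca = ex.qc_pca(v, res.samples)
        labels = [res.samples.tissue_of[s] for s in pca.coordinates.index]
        assert silhouette_score(pca.coordinates.values, labels) > 0.5

    def test_duplicated_sample_gets_identical_coordinates(self, rng):
        samples = _two_group_samples(3)
        base = rng.normal(size=(50, 6))
        base[:, 5] = base[:, 4]
        v = pd.DataFrame(base, columns=samples.samples)
        pca = ex.qc_pca(v, samples)
        assert np.allclose(
            pca.coordinates.iloc[4].values, pca.coordinates.iloc[5].values
        )

    def test_infinite_flag_threshold_flags_nothing(self, rng):
        samples = _two_group_samples(4)
        v = pd.DataFrame(rng.normal(size=(50, 8)), columns=samples.samples)
        assert ex.qc_pca(v, samples, flag_sd_multiple=np.inf).flagged == []

    def test_constant_matrix_rejected(self):
        samples = _two_group_samples(2)
        v = pd.DataFrame(np.ones((10, 4)), columns=samples.samples)
        with pytest.raises(ValueError):
            ex.qc_pca(v, samples)
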