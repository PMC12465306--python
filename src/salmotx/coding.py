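"""ORF discovery, k-let-preserving shuffles, and coding-potential scoring.

The lncRNA/mRNA discrimination follows the shuffle-negative strategy: for a
species without a curated lncRNA training set, negatives are generated by
shuffling the known mRNAs while preserving their k-mer composition (k = 7 by
default), so the classifier cannot separate the classes on nucleotide
composition alone and must rely on ORF structure.  A probabilistic classifier
on four features (transcript length, longest-ORF length, ORF coverage, and
in-frame hexamer usage bias) emits a coding potential score (CPS) in [0, 1];
the CPS cutoff is the value maximizing sensitivity + specificity over pooled
ten-fold cross-validation scores.
"""

from __future__ import annotations

import math
import random
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

STOPS = {"TAA", "TAG", "TGA"}
_NT = set("ACGTN")


@dataclass
class Orf:
    """A maximal start-to-stop open reading frame in transcript coordinates."""

    transcript_id: str
    frame: int
    start: int  # 1-based position of the A of ATG
    end: int  # 1-based inclusive end (last base of stop codon, or seq end)
    length_aa: int
    peptide: str
    domain_hit: bool = False
    complete: bool = True  # False for 3'-partial ORFs (no stop before seq end)

    @property
    def length_nt(self) -> int:
        return 3 * self.length_aa


def find_orfs(
    sequence: str, min_aa: int = 100, transcript_id: str = ""
) -> list[Orf]:
    """All maximal ATG-to-stop ORFs of at least ``min_aa`` amino acids.

    Only the three sense-strand frames are scanned (transcripts are
    stranded).  A codon containing N breaks any open ORF.  ORFs may be
    3'-partial (run off the transcript end without a stop); 5'-partial ORFs
    (no ATG) are not reported.  Result sorted by length descending.
    """
    seq = sequence.upper()
    if not set(seq) <= _NT:
        raise ValueError("sequence contains non-ACGTN characters")
    orfs: list[Orf] = []
    for frame in range(3):
        open_start: int | None = None
        i = frame
        while i + 3 <= len(seq):
            codon = seq[i : i + 3]
            if "N" in codon:
                open_start = None  # ambiguous codon breaks the ORF
            elif codon in STOPS:
                if open_start is not None:
                    orfs.append(
                        _make_orf(seq, transcript_id, frame, open_start, i + 3, True)
                    )
                    open_start = None
            elif codon == "ATG" and open_start is None:
                open_start = i
            i += 3
        if open_start is not None:  # 3'-partial
            orfs.append(_make_orf(seq, transcript_id, frame, open_start, i, False))
    orfs = [o for o in orfs if o.length_aa >= min_aa]
    orfs.sort(key=lambda o: (-o.length_aa, o.frame, o.start))
    return orfs


def _make_orf(
    seq: str, tid: str, frame: int, start0: int, end0: int, complete: bool
) -> Orf:
    coding = seq[start0 : end0 - 3] if complete else seq[start0:end0]
    peptide = str(Seq(coding).translate())
    return Orf(
        transcript_id=tid,
        frame=frame,
        start=start0 + 1,
        end=end0,
        length_aa=len(coding) // 3,
        peptide=peptide,
        complete=complete,
    )


def klet_shuffle(sequence: str, k: int = 7, seed: int | None = None) -> str:
    """Uniform-random shuffle preserving the exact k-mer multiset.

    Implements the Euler-path k-let shuffle: the sequence is a walk on the
    de Bruijn multigraph of its (k-1)-mers; a random arborescence toward the
    terminal vertex fixes each vertex's last outgoing edge, remaining edges
    are permuted uniformly, and the resulting Euler path is read off.  The
    output has identical length and identical k-mer counts for every k' <= k.
    """
    seq = sequence.upper()
    if not set(seq) <= _NT:
        raise ValueError("sequence contains non-ACGTN characters")
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(seq) <= k:
        return seq
    rng = random.Random(seed)
    if k == 1:
        chars = list(seq)
        rng.shuffle(chars)
        return "".join(chars)

    m = k - 1
    vertices = [seq[i : i + m] for i in range(len(seq) - m + 1)]
    edges: dict[str, list[str]] = {}
    for a, b in zip(vertices, vertices[1:]):
        edges.setdefault(a, []).append(b)
    first, last = vertices[0], vertices[-1]

    # random arborescence toward `last`: pick a random out-edge per vertex
    # and accept when every vertex reaches `last` through its pick
    distinct = sorted(edges)
    for _ in range(10_000):
        pick = {v: rng.choice(edges[v]) for v in distinct if v != last}
        ok = True
        for v in distinct:
            seen = set()
            u = v
            while u != last and u in pick:
                if u in seen:
                    ok = False
                    break
                seen.add(u)
                u = pick[u]
            if not ok or (u != last and u not in pick):
                ok = False
                break
        if ok:
            break
    else:  # pragma: no cover - bounded-retry guard
        raise RuntimeError("failed to sample an arborescence")

    walk_edges: dict[str, list[str]] = {}
    for v in distinct:
        rest = list(edges[v])
        if v != last:
            rest.remove(pick[v])
        rng.shuffle(rest)
        if v != last:
            rest.append(pick[v])
        walk_edges[v] = rest

    out = [first]
    pos = {v: 0 for v in distinct}
    u = first
    for _ in range(len(seq) - m):
        nxt = walk_edges[u][pos[u]]
        pos[u] += 1
        out.append(nxt[-1])
        u = nxt
    return "".join(out)


def kmer_counts(sequence: str, k: int) -> Counter:
    return Counter(sequence[i : i + k] for i in range(len(sequence) - k + 1))


@dataclass
class CodingPotentialResult:
    transcript_id: str
    cps: float
    features: tuple[float, float, float, float]
    label: str  # "coding" | "noncoding"


@dataclass
class CutoffReport:
    cutoff: float
    fold_sensitivity: list[float]
    fold_specificity: list[float]
    folds: int = 10


@dataclass
class HexamerModel:
    """In-frame hexamer usage bias: coding (longest-ORF frame) vs shuffled
    background.  Log-odds with add-one pseudocounts."""

    log_odds: dict[str, float]

    @classmethod
    def train(cls, coding_orfs: list[str], background: list[str]) -> "HexamerModel":
        cod = Counter()
        for orf in coding_orfs:
            for i in range(0, len(orf) - 5, 3):
                cod[orf[i : i + 6]] += 1
        bg = Counter()
        for s in background:
            bg.update(kmer_counts(s, 6))
        n_cod = sum(cod.values()) or 1
        n_bg = sum(bg.values()) or 1
        hexamers = set(cod) | set(bg)
        return cls(
            {
                h: math.log((cod[h] + 1) / (n_cod + 4096))
                - math.log((bg[h] + 1) / (n_bg + 4096))
                for h in hexamers
            }
        )

    def score(self, orf_nt: str) -> float:
        if len(orf_nt) < 6:
            return 0.0
        vals = [
            self.log_odds.get(orf_nt[i : i + 6], 0.0)
            for i in range(0, len(orf_nt) - 5, 3)
        ]
        return float(np.mean(vals)) if vals else 0.0


@dataclass
class CodingPotentialModel:
    pipeline: Pipeline
    hexamer: HexamerModel
    cutoff: float
    min_aa_feature: int = 1  # ORFs of any length feed the feature extractor

    def features_of(self, seq: str) -> tuple[float, float, float, float]:
        orfs = find_orfs(seq, min_aa=self.min_aa_feature)
        if orfs:
            longest = orfs[0]
            orf_nt = seq[longest.start - 1 : longest.start - 1 + longest.length_nt]
            hx = self.hexamer.score(orf_nt)
            return (
                float(len(seq)),
                float(longest.length_nt),
                longest.length_nt / len(seq),
                hx,
            )
        return (float(len(seq)), 0.0, 0.0, 0.0)

    def cps(self, seq: str) -> float:
        x = np.asarray([self.features_of(seq)])
        return float(self.pipeline.predict_proba(x)[0, 1])


def _pick_cutoff(scores: np.ndarray, labels: np.ndarray) -> float:
    """Smallest threshold (observed scores and midpoints of adjacent distinct
    scores) maximizing sensitivity + specificity, with label = coding iff
    CPS >= cutoff."""
    uniq = np.unique(scores)
    cands = np.concatenate([uniq, (uniq[:-1] + uniq[1:]) / 2.0])
    cands.sort()
    pos = labels == 1
    best_c, best_j = cands[0], -np.inf
    for c in cands:
        called = scores >= c
        sens = (called & pos).sum() / max(pos.sum(), 1)
        spec = (~called & ~pos).sum() / max((~pos).sum(), 1)
        if sens + spec > best_j + 1e-12:
            best_j, best_c = sens + spec, c
    return float(best_c)


def train_codpot(
    mrnas: list[str], k_shuffle: int = 7, seed: int | None = None
) -> tuple[CodingPotentialModel, CutoffReport]:
    """Train the CPS classifier with k-let-shuffled negatives.

    Each mRNA contributes one positive and one shuffled negative; the cutoff
    is selected on pooled out-of-fold scores from a stratified ten-fold
    cross-validation and is invariant to fold order by construction.
    """
    if len(mrnas) < 20:
        raise ValueError("need at least 20 training mRNAs")
    if len(set(mrnas)) == 1:
        raise ValueError("degenerate training set: all sequences identical")
    rng = random.Random(seed)
    negatives = [
        klet_shuffle(s, k=k_shuffle, seed=rng.randrange(2**31)) for s in mrnas
    ]
    orf_seqs = []
    for s in mrnas:
        orfs = find_orfs(s, min_aa=1)
        if orfs:
            o = orfs[0]
            orf_seqs.append(s[o.start - 1 : o.start - 1 + o.length_nt])
    hexamer = HexamerModel.train(orf_seqs, negatives)

    def make_pipeline() -> Pipeline:
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("logit", LogisticRegression(max_iter=2000)),
            ]
        )

    model = CodingPotentialModel(make_pipeline(), hexamer, cutoff=0.5)
    seqs = mrnas + negatives
    X = np.asarray([model.features_of(s) for s in seqs])
    y = np.asarray([1] * len(mrnas) + [0] * len(negatives))

    skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=seed)
    oof = np.zeros(len(y))
    for tr, te in skf.split(X, y):
        fold_pipe = make_pipeline()
        fold_pipe.fit(X[tr], y[tr])
        oof[te] = fold_pipe.predict_proba(X[te])[:, 1]
    cutoff = _pick_cutoff(oof, y)

    fold_sens, fold_spec = [], []
    for tr, te in skf.split(X, y):
        called = oof[te] >= cutoff
        pos = y[te] == 1
        fold_sens.append(float((called & pos).sum() / max(pos.sum(), 1)))
        fold_spec.append(float((~called & ~pos).sum() / max((~pos).sum(), 1)))

    model.pipeline.fit(X, y)
    model.cutoff = cutoff
    return model, CutoffReport(cutoff, fold_sens, fold_spec)


def score_transcripts(
    model: CodingPotentialModel, candidates: dict[str, str]
) -> list[CodingPotentialResult]:
    """Deterministic CPS and coding/noncoding label per candidate sequence."""
    results = []
    for tid, seq in candidates.items():
        feats = model.features_of(seq)
        cps = model.cps(seq)
        results.append(
            CodingPotentialResult(
                tid, cps, feats, "coding" if cps >= model.cutoff else "noncoding"
            )
        )
    return results


class MotifDomainScanner:
    """Built-in domain-evidence scanner: exact nucleotide motif matching.

    Stands behind the pluggable domain-evidence interface used by
    :func:`annotate_domains`; any object with a ``has_domain(orf_nt) -> bool``
    method can replace it (e.g. a profile-HMM wrapper).
    """

    def __init__(self, motifs: list[str]) -> None:
        self.motifs = [m.upper() for m in motifs]

    def has_domain(self, orf_nt: str) -> bool:
        return any(m in orf_nt for m in self.motifs)


def annotate_domains(
    orfs_by_transcript: dict[str, list[Orf]],
    sequences: dict[str, str],
    scanner: MotifDomainScanner,
) -> None:
    """Set ``domain_hit`` on each ORF by scanning its nucleotide span."""
    for tid, orfs in orfs_by_transcript.items():
        seq = sequences[tid]
        for o in orfs:
            orf_nt = seq[o.start - 1 : o.end]
            o.domain_hit = scanner.has_domain(orf_nt)


@dataclass
class LocusCategory:
    locus_id: str
    category: str  # known_coding | known_lncRNA | new_coding | lincRNA | excluded


MIN_LNCRNA_NT = 200


def categorize_loci(
    assembled,
    comparisons: dict,
    orfs_by_transcript: dict[str, list[Orf]],
    coding_results: list[CodingPotentialResult],
    reference,
) -> list[LocusCategory]:
    """Final locus triage.

    new_coding: every member transcript is intergenic ("u") and at least one
    member carries an ORF >= 100 aa with domain evidence.  lincRNA: every
    member is "u", no member is labeled coding by CPS or carries a
    domain-supported long ORF, and every member is >= 200 nt.  Loci with any
    reference-matching member inherit the matched reference biotype
    (known_coding / known_lncRNA); everything else is excluded.
    """
    label_of = {r.transcript_id: r.label for r in coding_results}
    cats: list[LocusCategory] = []
    for locus in assembled:
        if not locus.transcripts:
            raise ValueError(f"locus {locus.id} has no transcripts")
        codes = [comparisons[t.id].class_code for t in locus.transcripts]
        if all(c == "u" for c in codes):
            has_gated_orf = any(
                o.length_aa >= 100 and o.domain_hit
                for t in locus.transcripts
                for o in orfs_by_transcript.get(t.id, [])
            )
            if has_gated_orf:
                cats.append(LocusCategory(locus.id, "new_coding"))
            elif (
                all(label_of.get(t.id) == "noncoding" for t in locus.transcripts)
                and all(t.length >= MIN_LNCRNA_NT for t in locus.transcripts)
            ):
                cats.append(LocusCategory(locus.id, "lincRNA"))
            else:
                cats.append(LocusCategory(locus.id, "excluded"))
            continue
        ref_biotypes = {
            reference.transcripts[comparisons[t.id].ref_match].biotype
            for t in locus.transcripts
            if comparisons[t.id].ref_match in reference.transcripts
        }
        if "protein_coding" in ref_biotypes:
            cats.append(LocusCategory(locus.id, "known_coding"))
        elif "lncRNA" in ref_biotypes:
            cats.append(LocusCategory(locus.id, "known_lncRNA"))
        else:
            cats.append(LocusCategory(locus.id, "excluded"))
    return cats
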