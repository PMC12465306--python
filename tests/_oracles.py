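"""Independent brute-force oracles used to cross-check the implementation.

Every function here is written directly from the operation definitions, with
no interval indexes, vectorization, or shared code paths with the package.
"""

from __future__ import annotations

import math
from itertools import combinations

STOPS = {"TAA", "TAG", "TGA"}


# --- class codes --------------------------------------------------------


def _exons_overlap(a, b) -> bool:
    return any(
        ea.start <= eb.end and eb.start <= ea.end for ea in a.exons for eb in b.exons
    )


def _junctions(t):
    return {(x.end, y.start) for x, y in zip(t.exons, t.exons[1:])}


def brute_classify(asm, refs) -> str:
    """Class code by exhaustive pairwise checks over a list of reference
    transcripts (same contig assumed pre-filtered by caller)."""
    refs = [r for r in refs if r.contig == asm.contig]
    span_over = [
        r for r in refs if r.exons[0].start <= asm.exons[-1].end
        and asm.exons[0].start <= r.exons[-1].end
    ]
    same = [r for r in span_over if r.strand == asm.strand]
    anti = [r for r in span_over if r.strand != asm.strand]
    aj = _junctions(asm)

    for r in same:
        rj = _junctions(r)
        if aj and aj == rj:
            return "="
        if not aj and not rj and _exons_overlap(asm, r):
            return "="
    for r in same:
        if not _exons_overlap(asm, r):
            continue
        if asm.exons[0].start < r.exons[0].start or asm.exons[-1].end > r.exons[-1].end:
            continue
        rj = sorted(_junctions(r))
        ajs = sorted(aj)
        if not aj:
            if all(not (j0 >= asm.exons[0].start and j1 <= asm.exons[-1].end)
                   for j0, j1 in rj):
                return "c"
            continue
        if set(ajs) <= set(rj):
            i = rj.index(ajs[0])
            if rj[i : i + len(ajs)] == ajs:
                return "c"
    if aj and any(aj & _junctions(r) for r in same):
        return "j"
    same_exonic = [r for r in same if _exons_overlap(asm, r)]
    if not aj:
        for r in same_exonic:
            for e in r.exons:
                if e.start - 10 <= asm.exons[0].start and asm.exons[-1].end <= e.end + 10:
                    return "e"
    if same_exonic:
        return "o"
    for r in span_over:
        for x, y in zip(r.exons, r.exons[1:]):
            if x.end + 1 <= asm.exons[0].start and asm.exons[-1].end <= y.start - 1:
                return "i"
    if any(_exons_overlap(asm, r) for r in anti):
        return "x"
    if span_over:
        return "other"
    return "u"


# --- ORFs ---------------------------------------------------------------


def brute_orfs(seq: str, min_aa: int) -> list[tuple[int, int, int]]:
    """(frame, start codon index, length_aa) of maximal ATG-to-stop ORFs.

    A codon is a break when it is a stop or contains N.  Within each run of
    break-free codons, the first ATG opens the single maximal ORF of that
    run; it is emitted when the run ends in a stop or at the sequence end
    (3'-partial), and discarded when the run is terminated by an N codon.
    """
    out = []
    for frame in range(3):
        codons = [
            seq[i : i + 3]
            for i in range(frame, len(seq) - 2, 3)
        ]
        runs = []
        cur = []
        for idx, c in enumerate(codons):
            if c in STOPS:
                runs.append((cur, "stop"))
                cur = []
            elif "N" in c:
                runs.append((cur, "n"))
                cur = []
            else:
                cur.append(idx)
        runs.append((cur, "end"))
        for members, terminator in runs:
            if terminator == "n":
                continue
            starts = [i for i in members if codons[i] == "ATG"]
            if not starts:
                continue
            s = starts[0]
            length = members[-1] - s + 1
            if length >= min_aa:
                out.append((frame, s, length))
    return out


# --- tau ----------------------------------------------------------------


def brute_tau(x: list[float]) -> float:
    m = max(x)
    return sum(1.0 - xi / m for xi in x) / (len(x) - 1)


# --- TOM ----------------------------------------------------------------


def brute_tom(a) -> list[list[float]]:
    n = len(a)
    t = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                t[i][j] = 1.0
                continue
            l = sum(a[i][u] * a[u][j] for u in range(n) if u not in (i, j))
            ki = sum(a[i][u] for u in range(n) if u != i)
            kj = sum(a[j][u] for u in range(n) if u != j)
            t[i][j] = (l + a[i][j]) / (min(ki, kj) + 1.0 - a[i][j])
    return t


# --- hypergeometric tail ------------------------------------------------


def brute_hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws),
    by direct summation of binomial-coefficient ratios."""
    denom = math.comb(N, n)
    total = 0
    for x in range(k, min(K, n) + 1):
        if n - x > N - K:
            continue
        total += math.comb(K, x) * math.comb(N - K, n - x)
    return total / denom


def enumerate_hypergeom_tail(k: int, background: list[str], term: set[str], n: int) -> float:
    """P(|draw & term| >= k) by exhaustive enumeration of all n-subsets."""
    hits = 0
    total = 0
    for draw in combinations(background, n):
        total += 1
        if len(set(draw) & term) >= k:
            hits += 1
    return hits / total


# --- BH -----------------------------------------------------------------


def brute_bh(pvals: list[float]) -> list[float]:
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        val = min(prev, pvals[i] * m / rank_from_end)
        adj[i] = val
        prev = val
    return adj


# --- nearest partner ----------------------------------------------------


def brute_nearest(lnc, candidates, max_window: int):
    """Nearest same-contig transcript by boundary gap within max_window."""
    best = None
    for t in candidates:
        if t.contig != lnc.contig or t.id == lnc.id:
            continue
        gap = max(
            0,
            max(lnc.exons[0].start, t.exons[0].start)
            - min(lnc.exons[-1].end, t.exons[-1].end)
            - 1,
        )
        if gap > max_window:
            continue
        if best is None or gap < best[1]:
            best = (t, gap)
    return best
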