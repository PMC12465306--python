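"""Hypergeometric over-representation analysis of module gene sets.

The gene -> term mapping is supplied by the caller (for newly characterized
genes this typically comes from orthology transfer); no term database is
bundled.  For each term, the one-sided hypergeometric tail gives the
probability of drawing at least the observed overlap when sampling
module-size genes from the background; BH correction is applied across
terms within each module.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class EnrichmentResult:
    module: str
    term: str
    term_size: int
    overlap: int
    module_size: int
    background_size: int
    p: float
    fdr: float


def enrich(
    module_genes: set[str],
    background_genes: set[str],
    term_mapping: dict[str, set[str]],
    fdr_cutoff: float = 0.05,
    top_n: int = 10,
    module_name: str = "module",
) -> list[EnrichmentResult]:
    """Over-represented terms in a module at FDR < cutoff, capped at top_n.

    Ties in FDR are broken by raw p, then term id, so results are invariant
    to gene and term iteration order.
    """
    if not module_genes:
        return []
    if not module_genes <= background_genes:
        raise ValueError("module genes must be a subset of the background")
    n_bg = len(background_genes)
    n_mod = len(module_genes)
    rows = []
    for term in sorted(term_mapping):
        members = term_mapping[term] & background_genes
        if not members:
            continue
        overlap = len(term_mapping[term] & module_genes)
        # P(X >= overlap), X ~ Hypergeom(N=n_bg, K=|term|, n=n_mod)
        p = float(stats.hypergeom.sf(overlap - 1, n_bg, len(members), n_mod))
        rows.append((term, len(members), overlap, p))
    if not rows:
        return []
    fdrs = multipletests([r[3] for r in rows], method="fdr_bh")[1]
    results = [
        EnrichmentResult(
            module=module_name,
            term=term,
            term_size=term_size,
            overlap=overlap,
            module_size=n_mod,
            background_size=n_bg,
            p=p,
            fdr=float(fdr),
        )
        for (term, term_size, overlap, p), fdr in zip(rows, fdrs)
    ]
    results = [r for r in results if r.fdr < fdr_cutoff]
    results.sort(key=lambda r: (r.fdr, r.p, r.term))
    return results[:top_n]
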