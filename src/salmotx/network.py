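"""Unsigned weighted co-expression network and module detection.

Adjacency a_ij = |cor(i,j)|^beta (unsigned, so inverse relationships such as
lncRNA-target repression are as connected as positive co-expression), with
the soft power beta chosen as the smallest value whose network satisfies the
scale-free topology fit index R^2 > 0.8.  Topological overlap (TOM) measures
shared neighborhood; modules come from average-linkage clustering of
1 - TOM with a static cut, a minimum size floor, and iterative merging of
modules whose eigengenes correlate strongly.  Module detection here replaces
the hybrid dynamic tree cut of the reference WGCNA workflow with a simpler
deterministic procedure; parameters minModuleSize = 30 and
mergeCutHeight = 0.25 keep their conventional meaning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

# WGCNA's conventional module color sequence, assigned in decreasing size order
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
]
GREY = "grey"


def variance_filter(
    matrix: pd.DataFrame, keep_fraction: float = 0.75
) -> pd.DataFrame:
    """Retain the top ``keep_fraction`` of loci by expression variance."""
    if matrix.shape[0] < 4:
        raise ValueError("variance_filter requires at least 4 loci")
    if keep_fraction <= 0:
        raise ValueError("keep_fraction must be positive")
    if keep_fraction >= 1.0:
        return matrix
    variances = matrix.var(axis=1, ddof=1)
    if np.allclose(variances, 0):
        raise ValueError("constant matrix: no variance to rank")
    cut = variances.quantile(1.0 - keep_fraction)
    return matrix.loc[variances > cut]


@dataclass
class SoftThresholdResult:
    powers: list[int]
    r_squared: list[float]
    mean_connectivity: list[float]
    selected: int
    reached_target: bool


def _scale_free_r2(adj: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10 frequency vs log10 connectivity over binned k."""
    k = adj.sum(axis=1) - np.diag(adj)
    k = k[k > 0]
    if len(k) < n_bins or np.ptp(k) == 0:
        return 0.0
    # equal-width bins over the connectivity range (WGCNA convention)
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_f = [], []
    for b in range(n_bins):
        members = k[idx == b]
        if len(members) == 0:
            continue
        log_k.append(np.log10(members.mean()))
        log_f.append(np.log10(len(members) / len(k)))
    if len(log_k) < 3:
        return 0.0
    r = stats.pearsonr(log_k, log_f)[0]
    # signed fit index: only a decreasing frequency-connectivity relation
    # counts as scale-free (slope sign carried by r)
    return float(r**2) if r < 0 else -float(r**2)


def adjacency(matrix: pd.DataFrame, beta: int) -> pd.DataFrame:
    """a_ij = |pearson(i,j)|^beta with unit diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    variances = matrix.var(axis=1, ddof=1)
    if (variances == 0).any():
        raise ValueError("zero-variance locus present; apply variance_filter first")
    cor = np.corrcoef(matrix.values)
    adj = np.abs(cor) ** beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=matrix.index, columns=matrix.index)


def pick_soft_power(
    matrix: pd.DataFrame,
    powers: range = range(1, 21),
    target_r2: float = 0.8,
) -> SoftThresholdResult:
    """Smallest beta with scale-free fit R^2 above target; if none reaches
    the target, the argmax R^2 is returned with a warning."""
    if matrix.shape[0] < 30:
        raise ValueError("soft-power selection needs at least 30 loci")
    cor = np.abs(np.corrcoef(matrix.values))
    np.fill_diagonal(cor, 1.0)
    r2s, ks = [], []
    for beta in powers:
        adj = cor**beta
        r2s.append(_scale_free_r2(adj))
        ks.append(float((adj.sum(axis=1) - 1.0).mean()))
    selected = None
    for beta, r2 in zip(powers, r2s):
        if r2 > target_r2:
            selected = beta
            break
    reached = selected is not None
    if not reached:
        if max(r2s) >= 0.5:
            selected = list(powers)[int(np.argmax(r2s))]
        else:
            # no power shows even a moderately scale-free regime; the argmax
            # would chase binning noise, so fall back to the conventional
            # default power for unsigned networks
            selected = 6
        warnings.warn(
            f"no power reaches scale-free R^2 > {target_r2}; "
            f"using beta={selected}"
        )
    return SoftThresholdResult(list(powers), r2s, ks, selected, reached)


def tom(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) where
    l_ij = sum_{u not in {i,j}} a_iu * a_uj and k_i = sum_{u != i} a_iu;
    diagonal set to 1.
    """
    a = adj.values
    k = a.sum(axis=1) - np.diag(a)
    # full product then remove u = i and u = j contributions
    prod = a @ a
    l = prod - np.outer(np.diag(a), np.ones(len(a))) * a
    l = l - a * np.diag(a)[None, :]
    num = l + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    t = num / denom
    np.fill_diagonal(t, 1.0)
    return pd.DataFrame(t, index=adj.index, columns=adj.columns)


def module_eigengene(expr: pd.DataFrame) -> pd.Series:
    """First principal component of the standardized module expression,
    sign-oriented so it correlates positively with the module mean."""
    X = expr.values.astype(float)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    mean = X.mean(axis=1, keepdims=True)
    Z = (X - mean) / np.where(sd == 0, 1.0, sd)
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    me = vt[0]
    mean_profile = Z.mean(axis=0)
    if np.corrcoef(me, mean_profile)[0, 1] < 0:
        me = -me
    return pd.Series(me, index=expr.columns)


@dataclass
class ModuleDetection:
    modules: pd.Series  # locus -> color label ("grey" = unassigned)
    eigengenes: pd.DataFrame  # samples x module colors


def _auto_cut_height(link: np.ndarray, n_leaves: int, min_size: int) -> float:
    """Cut height maximizing the number of clusters of size >= min_size.

    Candidate heights are the midpoints between consecutive distinct merge
    heights; ties prefer the largest height (the coarsest partition), which
    leaves over-splitting to the eigengene merging step.
    """
    heights = np.unique(link[:, 2])
    cands = (heights[:-1] + heights[1:]) / 2.0
    cands = np.append(cands, heights[-1] + 1.0)
    best_h, best_n = cands[-1], -1
    for h in cands:
        labels = fcluster(link, t=h, criterion="distance")
        sizes = np.bincount(labels)
        n_big = int((sizes >= min_size).sum())
        if n_big >= best_n:
            best_n, best_h = n_big, h
    return float(best_h)


def detect_modules(
    dissimilarity: pd.DataFrame,
    expression: pd.DataFrame,
    min_module_size: int = 30,
    merge_cut_height: float = 0.25,
    cut_height_fraction: float | None = None,
) -> ModuleDetection:
    """Average-linkage clustering of 1 - TOM with static cut and merging.

    With ``cut_height_fraction`` None (default) the cut height is chosen
    automatically as the height maximizing the number of clusters of at
    least ``min_module_size`` loci; a float cuts statically at that fraction
    of the tree height.  Clusters below ``min_module_size`` go to grey;
    modules whose eigengene dissimilarity (1 - cor) is below
    ``merge_cut_height`` are merged iteratively until stable.  Colors are
    assigned in decreasing size order.
    """
    loci = list(dissimilarity.index)
    n = len(loci)
    if n < min_module_size:
        warnings.warn("fewer loci than min_module_size: everything is grey")
        return ModuleDetection(
            modules=pd.Series(GREY, index=loci),
            eigengenes=pd.DataFrame(index=expression.columns),
        )
    d = dissimilarity.values.copy()
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    link = average(squareform(d, checks=False))
    if cut_height_fraction is None:
        cut = _auto_cut_height(link, n, min_module_size)
    else:
        cut = cut_height_fraction * link[:, 2].max()
    labels = fcluster(link, t=cut, criterion="distance")

    clusters: dict[int, list[str]] = {}
    for locus, lab in zip(loci, labels):
        clusters.setdefault(int(lab), []).append(locus)
    kept = [ms for ms in clusters.values() if len(ms) >= min_module_size]
    grey = [m for ms in clusters.values() if len(ms) < min_module_size for m in ms]

    # iterative eigengene merging
    changed = True
    while changed and len(kept) > 1:
        changed = False
        mes = [module_eigengene(expression.loc[ms]) for ms in kept]
        best = None
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                diss = 1.0 - float(np.corrcoef(mes[i], mes[j])[0, 1])
                if diss < merge_cut_height and (best is None or diss < best[0]):
                    best = (diss, i, j)
        if best is not None:
            _, i, j = best
            kept[i] = kept[i] + kept[j]
            del kept[j]
            changed = True

    kept.sort(key=lambda ms: (-len(ms), sorted(ms)[0]))
    assignment = pd.Series(GREY, index=loci, dtype=object)
    eigengenes = {}
    for color, members in zip(MODULE_COLORS, kept):
        assignment[members] = color
        eigengenes[color] = module_eigengene(expression.loc[members])
    for locus in grey:
        assignment[locus] = GREY
    return ModuleDetection(
        modules=assignment,
        eigengenes=pd.DataFrame(eigengenes, index=expression.columns),
    )


@dataclass
class ModuleTraitTable:
    r: pd.DataFrame  # modules x tissues
    p: pd.DataFrame
    significant: pd.DataFrame  # |r| > 0.7 and p < 0.01


def module_trait(
    eigengenes: pd.DataFrame,
    samples,
    r_threshold: float = 0.7,
    p_threshold: float = 0.01,
) -> ModuleTraitTable:
    """Pearson correlation of each module eigengene with each tissue's
    one-vs-all indicator; p from the t distribution with n - 2 df."""
    if eigengenes.shape[0] < 3:
        raise ValueError("module_trait requires at least 3 samples")
    tissues = samples.tissues
    rows_r, rows_p = {}, {}
    for tissue in tissues:
        members = set(samples.samples_of(tissue))
        if len(members) < 2:
            warnings.warn(f"tissue {tissue!r} has <2 samples; column skipped")
            continue
        indicator = np.array(
            [1.0 if s in members else 0.0 for s in eigengenes.index]
        )
        r_col, p_col = {}, {}
        for module in eigengenes.columns:
            r, p = stats.pearsonr(eigengenes[module].values, indicator)
            r_col[module], p_col[module] = r, p
        rows_r[tissue] = pd.Series(r_col)
        rows_p[tissue] = pd.Series(p_col)
    r_df = pd.DataFrame(rows_r)
    p_df = pd.DataFrame(rows_p)
    return ModuleTraitTable(
        r=r_df,
        p=p_df,
        significant=(r_df.abs() > r_threshold) & (p_df < p_threshold),
    )
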