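"""Weighted co-expression modules and module-trait association.

The classic workflow: an unsigned adjacency a_ij = |cor(i, j)|^beta with the
soft power beta chosen as the smallest integer giving an approximately
scale-free connectivity distribution (fit R^2 above a target, negative
slope); a topological-overlap measure (TOM) between genes; average-linkage
hierarchical clustering on the TOM dissimilarity; and a fixed-height cut
chosen by scanning cut heights for the partition of maximal weighted
modularity (a deterministic stand-in for dynamic tree cutting).  Each
module's eigengene is the first principal component of the standardized
member expression, sign-oriented so members correlate positively with it on
average; module-trait relationships are Pearson correlations of eigengene
versus trait with Student-t p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

log = logging.getLogger("lncmast")

# WGCNA's conventional module color order; "grey" is reserved for unassigned
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue",
]


@dataclass
class SoftThresholdResult:
    beta: int
    r2: float
    candidates: pd.DataFrame  # columns: beta, r2, slope, mean_connectivity


@dataclass
class GeneNetworkModule:
    module_id: str
    members: list[str]
    eigengene: pd.Series | None = None
    trait_cor: dict[str, tuple[float, float]] = field(default_factory=dict)


def adjacency_matrix(expr: pd.DataFrame, beta: float) -> np.ndarray:
    """Unsigned adjacency |cor|^beta between genes (expr: genes x samples)."""
    with np.errstate(invalid="ignore"):
        cor = np.corrcoef(expr.values)
    cor = np.nan_to_num(cor, nan=0.0)
    adj = np.abs(cor) ** beta
    np.fill_diagonal(adj, 1.0)
    return adj


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """R^2 and slope of log10 p(k) vs log10 mean(k) over connectivity bins."""
    k = k[k > 0]
    if len(k) < n_bins or np.ptp(k) == 0:
        return np.nan, np.nan
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() > 0:
            xs.append(np.log10(k[mask].mean()))
            ys.append(np.log10(mask.sum() / len(k)))
    if len(xs) < 3:
        return np.nan, np.nan
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(r**2), float(slope)


def pick_soft_threshold(expr: pd.DataFrame, betas=range(1, 21),
                        r2_target: float = 0.9) -> SoftThresholdResult:
    """Pick the smallest soft power whose connectivity distribution fits a
    power law with R^2 > r2_target and negative slope.

    If no candidate passes, the beta with maximal R^2 is returned with a
    warning.  Requires at least 4 samples.
    """
    if expr.shape[1] < 4:
        raise ValueError("pick_soft_threshold: need >= 4 samples")
    with np.errstate(invalid="ignore"):
        cor = np.corrcoef(expr.values)
    cor = np.abs(np.nan_to_num(cor, nan=0.0))
    np.fill_diagonal(cor, 0.0)
    rows = []
    for beta in betas:
        k = (cor**beta).sum(axis=1)
        r2, slope = _scale_free_fit(k)
        rows.append({"beta": int(beta), "r2": r2, "slope": slope,
                     "mean_connectivity": float(k.mean())})
    cand = pd.DataFrame(rows)
    ok = cand[(cand["r2"] > r2_target) & (cand["slope"] < 0)]
    if len(ok):
        row = ok.iloc[0]
    else:
        if cand["r2"].isna().all():
            log.warning("pick_soft_threshold: scale-free fit undefined "
                        "(degenerate connectivity); using beta=%d",
                        int(cand["beta"].iloc[0]))
            row = cand.iloc[0]
        else:
            log.warning("pick_soft_threshold: no beta reaches R2 > %.2f; "
                        "using the best fit", r2_target)
            row = cand.loc[cand["r2"].idxmax()]
    return SoftThresholdResult(int(row["beta"]),
                               float(row["r2"]) if np.isfinite(row["r2"]) else np.nan,
                               cand)


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix: TOM_ij = (L_ij + a_ij) /
    (min(k_i, k_j) + 1 - a_ij) with L the shared-neighbor weight; unit
    diagonal."""
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    L = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (L + a) / (kmin + 1.0 - a)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def _modularity(adj: np.ndarray, labels: np.ndarray) -> float:
    """Weighted Newman modularity; unassigned genes (label 0) count as
    singleton communities."""
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    two_m = a.sum()
    if two_m == 0:
        return 0.0
    k = a.sum(axis=1)
    labs = labels.copy()
    grey = labs == 0
    labs[grey] = -np.arange(1, grey.sum() + 1)  # singletons
    q = 0.0
    for lab in np.unique(labs):
        mask = labs == lab
        q += a[np.ix_(mask, mask)].sum() / two_m - (k[mask].sum() / two_m) ** 2
    return float(q)


def detect_modules(expr: pd.DataFrame, beta: float,
                   min_module_size: int = 30,
                   n_heights: int = 25) -> list[GeneNetworkModule]:
    """Cluster genes into co-expression modules.

    Average-linkage hierarchical clustering on 1 - TOM; the cut height is
    chosen deterministically by scanning ``n_heights`` quantiles of the
    merge heights and keeping the partition with the largest weighted
    modularity (clusters below ``min_module_size`` fall into "grey").
    Modules are labeled with the conventional color ladder by decreasing
    size.
    """
    genes = list(expr.index)
    adj = adjacency_matrix(expr, beta)
    tom = tom_similarity(adj)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    heights = np.quantile(Z[:, 2], np.linspace(0.3, 0.99, n_heights))
    best_labels, best_q = np.zeros(len(genes), dtype=int), -np.inf
    for h in heights:
        raw = fcluster(Z, t=h, criterion="distance")
        labels = np.zeros(len(genes), dtype=int)
        next_id = 1
        for lab in np.unique(raw):
            mask = raw == lab
            if mask.sum() >= min_module_size:
                labels[mask] = next_id
                next_id += 1
        if labels.max() == 0:
            continue
        q = _modularity(adj, labels)
        if q > best_q + 1e-12:
            best_labels, best_q = labels, q
    modules = []
    sizes = [(lab, int((best_labels == lab).sum()))
             for lab in np.unique(best_labels) if lab != 0]
    sizes.sort(key=lambda x: (-x[1], x[0]))
    for rank, (lab, _size) in enumerate(sizes):
        color = (MODULE_COLORS[rank] if rank < len(MODULE_COLORS)
                 else f"module{rank + 1}")
        members = [g for g, m in zip(genes, best_labels == lab) if m]
        modules.append(GeneNetworkModule(color, members))
    grey = [g for g, lab in zip(genes, best_labels) if lab == 0]
    if grey:
        modules.append(GeneNetworkModule("grey", grey))
    return modules


def eigengene(expr: pd.DataFrame, members: list[str]) -> pd.Series:
    """First principal component of the standardized member expression,
    one score per sample, oriented so the mean member correlation with the
    eigengene is positive."""
    sub = expr.loc[members].values.astype(float)
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    zmat = (sub - mu) / sd
    _, _, vt = np.linalg.svd(zmat, full_matrices=False)
    me = vt[0]
    if np.mean(zmat @ me) < 0:
        me = -me
    return pd.Series(me, index=expr.columns, name="ME")


def module_trait(modules: list[GeneNetworkModule], expr: pd.DataFrame,
                 sample_traits: pd.DataFrame,
                 p_thr: float = 0.05) -> pd.DataFrame:
    """Correlate each module eigengene with each trait column.

    ``sample_traits``: samples x traits (group one-hot indicators and/or
    SCC).  Fills ``module.eigengene`` and ``module.trait_cor`` in place and
    returns a long table (module, trait, r, pvalue, significant).  Constant
    traits yield NA."""
    n = expr.shape[1]
    rows = []
    for mod in modules:
        if mod.module_id == "grey" or not mod.members:
            continue
        me = eigengene(expr, mod.members)
        mod.eigengene = me
        for trait in sample_traits.columns:
            tv = sample_traits.loc[me.index, trait].values.astype(float)
            if np.std(tv) == 0 or np.std(me.values) == 0:
                r, p = np.nan, np.nan
            else:
                r = float(np.corrcoef(me.values, tv)[0, 1])
                r = float(np.clip(r, -1.0, 1.0))
                if abs(r) >= 1.0:
                    p = np.finfo(float).tiny
                else:
                    t = r * np.sqrt((n - 2) / (1.0 - r**2))
                    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
            mod.trait_cor[trait] = (r, p)
            rows.append({"module": mod.module_id, "trait": trait, "r": r,
                         "pvalue": p,
                         "significant": bool(p < p_thr) if np.isfinite(p) else False})
    return pd.DataFrame(rows, columns=["module", "trait", "r", "pvalue",
                                       "significant"])
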