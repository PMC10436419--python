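"""Negative-binomial differential expression for count matrices.

A deliberately compact re-implementation of the standard bulk RNA-seq
workflow: low-count prefiltering, median-of-ratios size factors, a
log2(normalized + 1) expression transform, per-feature negative-binomial
Wald tests with moment dispersion estimates shrunk toward the across-feature
mean, and Benjamini-Hochberg adjustment.

Differential calling follows the strict thresholds used throughout the
analysis: |log2 fold change| > 1 and raw p < 0.05 (the adjusted p-value is
reported alongside but does not gate the call).  This is not a DESeq2
clone — no Cook's outlier handling, no fold-change shrinkage — and exact
numerical agreement with DESeq2 is a non-goal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger("lncmast")

COMPARISONS = {"SFvsSC": ("SF", "SC"), "HFvsHC": ("HF", "HC")}
"""Named comparisons: treatment group first, control second."""


def prefilter_counts(counts: pd.DataFrame, min_count: int = 10,
                     min_samples: int = 2) -> pd.DataFrame:
    """Keep features with count >= min_count in at least min_samples samples."""
    keep = (counts.values >= min_count).sum(axis=1) >= min_samples
    return counts.loc[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample normalization factors.

    factor_s = median over all-positive features of count_fs / geometric
    mean of the feature across samples.  If no feature is positive in every
    sample, falls back to total-count ratios with a warning.
    """
    mat = counts.values.astype(float)
    allpos = (mat > 0).all(axis=1)
    if allpos.any():
        logmat = np.log(mat[allpos])
        loggeo = logmat.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logmat - loggeo, axis=0))
    else:
        log.warning("size_factors: no feature positive in all samples; "
                    "falling back to total-count ratios")
        totals = mat.sum(axis=0)
        factors = totals / np.exp(np.mean(np.log(totals)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_log(counts: pd.DataFrame,
                   factors: pd.Series | None = None) -> pd.DataFrame:
    """log2(count / size_factor + 1), a simple variance-flattening transform
    standing in for regularized-log normalization."""
    if factors is None:
        factors = size_factors(counts)
    return np.log2(counts.div(factors, axis=1) + 1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEResult:
    feature_id: str
    comparison: str
    base_mean: float
    log2fc: float
    pvalue: float
    padj: float
    status: str = "ns"


def nb_wald_test(counts: pd.DataFrame, groups: pd.Series,
                 comparison: str | tuple[str, str],
                 pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-feature negative-binomial Wald test for one two-group comparison.

    Counts are normalized by median-of-ratios size factors.  The NB
    dispersion of each feature is estimated by the method of moments from
    within-group variances and shrunk 50/50 toward the mean dispersion over
    features (a simple stabilizer for small n).  The Wald statistic is
    z = log2FC / se with a delta-method standard error; p-values are
    two-sided normal, adjusted by Benjamini-Hochberg over the tested
    features.

    Features where one group is all zero get the fold change from the
    pseudocount policy and p = 1 (no test).
    """
    if isinstance(comparison, str):
        name, (treat, ctrl) = comparison, COMPARISONS[comparison]
    else:
        treat, ctrl = comparison
        name = f"{treat}vs{ctrl}"
    t_samples = groups.index[groups == treat]
    c_samples = groups.index[groups == ctrl]
    if len(t_samples) < 2 or len(c_samples) < 2:
        raise ValueError(
            f"comparison {name}: need >= 2 samples per group, got "
            f"{len(t_samples)} vs {len(c_samples)}"
        )
    sub = counts[list(t_samples) + list(c_samples)]
    sf = size_factors(sub)
    q = sub.div(sf, axis=1).values
    nt, nc = len(t_samples), len(c_samples)
    qt, qc = q[:, :nt], q[:, nt:]
    mu_t = qt.mean(axis=1)
    mu_c = qc.mean(axis=1)

    # method-of-moments dispersion from within-group variances:
    # Var(q_fs) = mu/sf_s + alpha * mu^2  =>  alpha = (s2 - mu*E[1/sf]) / mu^2
    inv_t = float(np.mean(1.0 / sf.values[:nt]))
    inv_c = float(np.mean(1.0 / sf.values[nt:]))
    with np.errstate(divide="ignore", invalid="ignore"):
        a_t = (qt.var(axis=1, ddof=1) - mu_t * inv_t) / np.where(mu_t > 0, mu_t**2, 1.0)
        a_c = (qc.var(axis=1, ddof=1) - mu_c * inv_c) / np.where(mu_c > 0, mu_c**2, 1.0)
    # keep the raw moment estimates unclipped: under near-zero dispersion
    # they are symmetric noise around 0, and clipping them (or the shrunk
    # value) at 0 would bias the variance up and make the test
    # conservative; negativity is tolerated here and floored only at the
    # variance level below
    alpha_raw = ((nt - 1) * a_t + (nc - 1) * a_c) / (nt + nc - 2)
    alpha_raw = np.where(np.isfinite(alpha_raw), alpha_raw, 0.0)
    alpha_trend = max(0.0, float(alpha_raw.mean())) if len(alpha_raw) else 0.0
    alpha = 0.5 * alpha_raw + 0.5 * alpha_trend

    zero_t = (qt == 0).all(axis=1)
    zero_c = (qc == 0).all(axis=1)
    untestable = zero_t | zero_c

    lfc = np.log2((mu_t + np.where(untestable, pseudocount, 0.0)) /
                  (mu_c + np.where(untestable, pseudocount, 0.0)))
    # Poisson floor: the NB variance can never drop below the counting noise
    var_mean_t = np.maximum(mu_t * inv_t / nt + alpha * mu_t**2 / nt,
                            0.5 * mu_t * inv_t / nt)
    var_mean_c = np.maximum(mu_c * inv_c / nc + alpha * mu_c**2 / nc,
                            0.5 * mu_c * inv_c / nc)
    ln2sq = np.log(2.0) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(
            var_mean_t / np.where(mu_t > 0, mu_t**2, np.inf)
            + var_mean_c / np.where(mu_c > 0, mu_c**2, np.inf)
        ) / np.sqrt(ln2sq)
        z = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    # the 50/50-shrunk variance estimate has a quarter of the sampling
    # variance of the raw (nt+nc-2)-df moment estimate, i.e. ~4x the
    # effective degrees of freedom by Satterthwaite, so a t reference with
    # 4*(nt+nc-2) df is used rather than a normal one
    df_eff = 4 * (nt + nc - 2)
    pvalue = 2.0 * stats.t.sf(np.abs(z), df=df_eff)
    pvalue = np.clip(pvalue, np.finfo(float).tiny, 1.0)
    pvalue[untestable] = 1.0
    res = pd.DataFrame(
        {
            "feature_id": counts.index,
            "comparison": name,
            "baseMean": q.mean(axis=1),
            "log2fc": lfc,
            "pvalue": pvalue,
        }
    )
    res["padj"] = np.maximum(bh_adjust(res["pvalue"].values), res["pvalue"].values)
    res["status"] = "ns"
    return res


def call_de(results: pd.DataFrame, lfc_thr: float = 1.0,
            p_thr: float = 0.05) -> pd.DataFrame:
    """Label each feature up/down/ns with strict thresholds:
    up iff log2fc > lfc_thr and p < p_thr; down symmetric."""
    res = results.copy()
    up = (res["log2fc"] > lfc_thr) & (res["pvalue"] < p_thr)
    down = (res["log2fc"] < -lfc_thr) & (res["pvalue"] < p_thr)
    res["status"] = np.where(up, "up", np.where(down, "down", "ns"))
    return res


def de_set(results: pd.DataFrame) -> set[str]:
    """Feature ids called differential (status != ns)."""
    return set(results.loc[results["status"] != "ns", "feature_id"])


def shared_de(set_a: pd.DataFrame, set_b: pd.DataFrame) -> pd.DataFrame:
    """Features differential in both comparisons, with per-comparison signs.

    Commutative and idempotent on the feature set; ``concordant`` flags
    pairs whose fold-change signs agree.
    """
    a = set_a.loc[set_a["status"] != "ns", ["feature_id", "log2fc", "status"]]
    b = set_b.loc[set_b["status"] != "ns", ["feature_id", "log2fc", "status"]]
    merged = a.merge(b, on="feature_id", suffixes=("_a", "_b"))
    merged["concordant"] = (
        np.sign(merged["log2fc_a"]) == np.sign(merged["log2fc_b"])
    )
    return merged.sort_values("feature_id", ignore_index=True)
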