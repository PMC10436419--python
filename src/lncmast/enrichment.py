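"""Over-representation analysis of gene lists against GMT gene sets.

One-sided hypergeometric tests (upper tail), Benjamini-Hochberg adjusted
across the tested terms.  The universe defaults to the expressed genes —
everything that survived the count prefilter — rather than the whole
annotation, the standard bias control for RNA-seq ORA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diff_expr import bh_adjust

log = logging.getLogger("lncmast")


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # overlap: study genes in the term
    K: int  # term size within the universe
    n: int  # study size
    N: int  # universe size
    pvalue: float
    padj: float = 1.0


def ora(
    study_genes: set[str],
    gmt: dict[str, tuple[str, frozenset[str]]],
    universe: set[str],
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``study_genes`` in each GMT term.

    Terms are intersected with the universe first; the study set must be a
    subset of the universe.  p = P[X >= k] with
    X ~ Hypergeometric(N, K, n).  Returns results sorted by p-value with BH
    adjustment across the tested (non-empty) terms.
    """
    if not universe:
        raise ValueError("ora: empty universe")
    extra = study_genes - universe
    if extra:
        raise ValueError(
            f"ora: study genes outside the universe: {sorted(extra)[:5]}"
        )
    if not study_genes:
        return []
    N, n = len(universe), len(study_genes)
    results = []
    for term_id in sorted(gmt):
        desc, members = gmt[term_id]
        term_genes = set(members) & universe
        K = len(term_genes)
        if K == 0:
            continue
        k = len(study_genes & term_genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(term_id, desc, k, K, n, N,
                                        min(max(p, np.finfo(float).tiny), 1.0)))
    if results:
        adj = bh_adjust([r.pvalue for r in results])
        for r, a in zip(results, adj):
            r.padj = float(a)
    results.sort(key=lambda r: (r.pvalue, r.term_id))
    return results


def ora_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "term_id": r.term_id, "term_name": r.term_name, "k": r.k,
            "K": r.K, "n": r.n, "N": r.N, "pvalue": r.pvalue, "padj": r.padj,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "K", "n", "N",
                       "pvalue", "padj"],
    )


def significant_terms(results: list[EnrichmentResult],
                      padj_thr: float = 0.05) -> list[EnrichmentResult]:
    """Terms passing the adjusted-p threshold (0.01 is conventional for
    GO-style sets, 0.05 for pathway-style sets)."""
    return [r for r in results if r.padj < padj_thr]
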