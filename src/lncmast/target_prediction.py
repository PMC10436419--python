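"""Cis/trans target prediction for differentially expressed lncRNAs.

* **cis** targets: protein-coding genes whose genomic span lies within a
  window (default 100 kb) of the lncRNA span on the same chromosome,
  strand-ignored.  The gap between two intervals is
  ``max(0, max(starts) - min(ends))`` — zero when they overlap.
* **trans** targets: genes whose normalized log expression correlates with
  the lncRNA across the samples of one comparison (default |R| > 0.95,
  p < 0.05, two-sided Student-t transform of the Pearson coefficient).
* **binding screen**: a deliberately simplified duplex-energy scan
  (nearest-neighbor stacking over the best antiparallel complementary
  stretch, no loops or bulges) standing in for a full RNA-RNA interaction
  predictor.  The normalized free energy ndG = dG_min / min(sequence
  lengths); pairs with ndG < -0.08 are flagged as bound.  The energy table
  is approximate; the screen ranks candidate pairs but is not
  thermodynamically accurate.
* **SCC regression**: ordinary least squares of target-gene expression on
  the somatic cell count phenotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger("lncmast")


def interval_gap(start_a: int, end_a: int, start_b: int, end_b: int) -> int:
    """Base-pair gap between two 1-based inclusive intervals; 0 if they
    overlap.  Symmetric in the two intervals."""
    return max(0, max(start_a, start_b) - min(end_a, end_b))


@dataclass
class TargetPair:
    lnc_id: str
    gene_id: str
    mode: str  # cis | trans | both
    distance: int | None = None
    near_1kb: bool = False
    pcc: float | None = None
    pcc_p: float | None = None
    ndg: float | None = None
    bound: bool | None = None


def cis_targets(
    de_lnc_spans: dict[str, tuple[str, int, int]],
    gene_spans: dict[str, tuple[str, int, int]],
    window: int = 100_000,
) -> list[TargetPair]:
    """Genes within ``window`` bp of each DE lncRNA span (same chromosome).

    ``de_lnc_spans`` / ``gene_spans`` map id -> (chrom, start, end).
    Pairs at <= 1 kb are additionally flagged ``near_1kb``.
    """
    by_chrom: dict[str, list[tuple[str, int, int]]] = {}
    for gid, (chrom, s, e) in gene_spans.items():
        by_chrom.setdefault(chrom, []).append((gid, s, e))
    pairs = []
    for lnc_id in sorted(de_lnc_spans):
        chrom, ls, le = de_lnc_spans[lnc_id]
        for gid, gs, ge in sorted(by_chrom.get(chrom, [])):
            gap = interval_gap(ls, le, gs, ge)
            if gap <= window:
                pairs.append(
                    TargetPair(lnc_id, gid, "cis", distance=gap,
                               near_1kb=gap <= 1000)
                )
    return pairs


def pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value of a Pearson coefficient via the Student-t
    transform t = r * sqrt((n-2) / (1-r^2)), df = n - 2."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    return np.clip(2.0 * stats.t.sf(np.abs(t), df=n - 2),
                   np.finfo(float).tiny, 1.0)


def trans_targets(
    norm_expr: pd.DataFrame,
    de_lnc_ids: list[str],
    de_mrna_ids: list[str],
    samples: list[str],
    r_thr: float = 0.95,
    p_thr: float = 0.05,
) -> list[TargetPair]:
    """lncRNA-mRNA pairs with |Pearson R| > r_thr and p < p_thr over the
    given comparison samples.  Zero-variance features are skipped with a
    log entry.  Requires >= 3 samples."""
    if len(samples) < 3:
        raise ValueError("trans_targets: need >= 3 samples")
    lncs = [i for i in de_lnc_ids if i in norm_expr.index]
    genes = [g for g in de_mrna_ids if g in norm_expr.index]
    if not lncs or not genes:
        return []
    lx = norm_expr.loc[lncs, samples].values.astype(float)
    gx = norm_expr.loc[genes, samples].values.astype(float)
    n = len(samples)

    def _standardize(mat, names):
        sd = mat.std(axis=1)
        keep = sd > 0
        for name, ok in zip(names, keep):
            if not ok:
                log.info("trans_targets: %s has zero variance; skipped", name)
        z = (mat[keep] - mat[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
        return z, [nm for nm, ok in zip(names, keep) if ok]

    lz, lnames = _standardize(lx, lncs)
    gz, gnames = _standardize(gx, genes)
    if not lnames or not gnames:
        return []
    rmat = (lz @ gz.T) / n
    pmat = pearson_p(rmat, n)
    pairs = []
    for i, lnc in enumerate(lnames):
        for j, gene in enumerate(gnames):
            if lnc == gene:
                continue
            if abs(rmat[i, j]) > r_thr and pmat[i, j] < p_thr:
                pairs.append(
                    TargetPair(lnc, gene, "trans",
                               pcc=float(rmat[i, j]), pcc_p=float(pmat[i, j]))
                )
    return pairs


def merge_target_modes(pairs: list[TargetPair]) -> list[TargetPair]:
    """Collapse duplicate (lnc, gene) pairs; a pair seen both cis and trans
    appears once with mode "both" and both evidence fields populated."""
    merged: dict[tuple[str, str], TargetPair] = {}
    for p in pairs:
        key = (p.lnc_id, p.gene_id)
        if key not in merged:
            merged[key] = TargetPair(**vars(p))
            continue
        m = merged[key]
        if m.mode != p.mode:
            m.mode = "both"
        if p.distance is not None:
            m.distance, m.near_1kb = p.distance, p.near_1kb
        if p.pcc is not None:
            m.pcc, m.pcc_p = p.pcc, p.pcc_p
        if p.ndg is not None:
            m.ndg, m.bound = p.ndg, p.bound
    return [merged[k] for k in sorted(merged)]


# ---------------------------------------------------------------------------
# Simplified duplex-energy binding screen
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

# Approximate Watson-Crick nearest-neighbor stacking free energies
# (kcal/mol at 37C), keyed by the 5'->3' dinucleotide of the top strand.
# Symmetric under reverse-complement of the key; not thermodynamically
# exact, by design.
STACK_ENERGY = {
    "AA": -0.93, "UU": -0.93,
    "AU": -1.10,
    "UA": -1.33,
    "CU": -2.08, "AG": -2.08,
    "CA": -2.11, "UG": -2.11,
    "GA": -2.35, "UC": -2.35,
    "GU": -2.24, "AC": -2.24,
    "CG": -2.36,
    "GG": -3.26, "CC": -3.26,
    "GC": -3.42,
}


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def revcomp_rna(seq: str) -> str:
    return _to_rna(seq).translate(_COMPLEMENT)[::-1]


def duplex_min_energy(lnc_seq: str, target_seq: str) -> float:
    """Minimum stacking free energy over every antiparallel ungapped
    alignment of the two sequences, taking the best contiguous fully
    complementary stretch (no loops, no bulges).  More negative = stronger
    predicted pairing; 0.0 if no stack of two consecutive pairs exists."""
    s = _to_rna(lnc_seq)
    t = revcomp_rna(target_seq)  # equality with s now means a WC pair
    ns, nt = len(s), len(t)
    s_arr = np.frombuffer(s.encode(), dtype=np.uint8)
    t_arr = np.frombuffer(t.encode(), dtype=np.uint8)
    # stack energy of s positions (k, k+1) when both are paired
    es = np.array(
        [STACK_ENERGY.get(s[k:k + 2], 0.0) for k in range(ns - 1)],
        dtype=float,
    )
    big = 1e6  # breaks Kadane segments at non-paired positions
    best = 0.0
    for shift in range(-(nt - 1), ns):
        i0, i1 = max(0, shift), min(ns, shift + nt)
        if i1 - i0 < 2:
            continue
        j0 = i0 - shift
        match = s_arr[i0:i1] == t_arr[j0:j0 + (i1 - i0)]
        valid = match[:-1] & match[1:]
        seg = np.where(valid, es[i0:i1 - 1], big)
        # minimum-sum contiguous segment via prefix sums
        c = np.concatenate(([0.0], np.cumsum(seg)))
        running_max = np.maximum.accumulate(c[:-1])
        mins = c[1:] - running_max
        m = mins.min()
        if m < best:
            best = float(m)
    return best


def ndg_screen(lnc_seq: str, target_seq: str,
               ndg_thr: float = -0.08) -> tuple[float, bool]:
    """Normalized duplex free energy and binding call for one pair.

    ndG = dG_min / min(len(lnc), len(target)); bound iff ndG < ndg_thr
    (strict).  Sequences must be >= 20 nt."""
    if len(lnc_seq) < 20 or len(target_seq) < 20:
        raise ValueError("ndg_screen: sequences must be >= 20 nt")
    dg = duplex_min_energy(lnc_seq, target_seq)
    ndg = dg / min(len(lnc_seq), len(target_seq))
    return float(ndg), bool(ndg < ndg_thr)


def screen_pairs(pairs: list[TargetPair], sequences: dict[str, str],
                 ndg_thr: float = -0.08, max_len: int = 1500) -> None:
    """Run the ndG screen over target pairs in place.

    Sequences are truncated to ``max_len`` nt to bound the O(n*m) scan;
    pairs with a missing sequence are left unscreened."""
    for p in pairs:
        ls = sequences.get(p.lnc_id)
        ts = sequences.get(p.gene_id)
        if ls is None or ts is None or len(ls) < 20 or len(ts) < 20:
            continue
        p.ndg, p.bound = ndg_screen(ls[:max_len], ts[:max_len], ndg_thr)


def scc_regression(expr_values: pd.Series | np.ndarray,
                   scc: pd.Series | np.ndarray) -> tuple[float, float, float]:
    """OLS of one gene's expression on the SCC phenotype.

    Returns (slope, r, p) with the two-sided p-value on the slope.
    Requires >= 3 samples and non-constant SCC."""
    x = np.asarray(scc, dtype=float)
    y = np.asarray(expr_values, dtype=float)
    if len(x) < 3:
        raise ValueError("scc_regression: need >= 3 samples")
    if np.std(x) == 0:
        raise ValueError("scc_regression: SCC is constant")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue), float(res.pvalue)


def target_table(pairs: list[TargetPair]) -> pd.DataFrame:
    rows = [
        {
            "lnc_id": p.lnc_id, "gene_id": p.gene_id, "mode": p.mode,
            "distance": p.distance if p.distance is not None else np.nan,
            "near_1kb": p.near_1kb,
            "pcc": p.pcc if p.pcc is not None else np.nan,
            "pcc_p": p.pcc_p if p.pcc_p is not None else np.nan,
            "ndg": p.ndg if p.ndg is not None else np.nan,
            "bound": p.bound,
        }
        for p in pairs
    ]
    return pd.DataFrame(
        rows, columns=["lnc_id", "gene_id", "mode", "distance", "near_1kb",
                       "pcc", "pcc_p", "ndg", "bound"],
    ).sort_values(["lnc_id", "gene_id"], ignore_index=True)


def build_network(pairs: list[TargetPair], de_status: dict[str, str],
                  pathway_hits: dict[str, set[str]] | None = None) -> pd.DataFrame:
    """Tripartite lncRNA-gene-pathway edge list.

    ``de_status`` maps feature id -> up/down/ns for node annotation;
    ``pathway_hits`` maps pathway/term name -> member genes (only genes that
    are targets contribute gene-pathway edges).  Deterministic ordering."""
    rows = []
    target_genes = set()
    for p in sorted(pairs, key=lambda p: (p.lnc_id, p.gene_id)):
        rows.append({
            "source": p.lnc_id, "target": p.gene_id, "edge_type": "lnc-gene",
            "mode": p.mode,
            "source_status": de_status.get(p.lnc_id, "ns"),
            "target_status": de_status.get(p.gene_id, "ns"),
        })
        target_genes.add(p.gene_id)
    for pathway in sorted(pathway_hits or {}):
        for gene in sorted((pathway_hits or {})[pathway] & target_genes):
            rows.append({
                "source": gene, "target": pathway, "edge_type": "gene-pathway",
                "mode": "", "source_status": de_status.get(gene, "ns"),
                "target_status": "",
            })
    return pd.DataFrame(
        rows, columns=["source", "target", "edge_type", "mode",
                       "source_status", "target_status"],
    )
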