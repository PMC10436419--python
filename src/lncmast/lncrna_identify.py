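"""Identification of putative lncRNAs from assembled transcripts.

The filter cascade mirrors the standard discovery pipeline for bovine
RNA-seq assemblies:

1. structural filter — at least two exons (known reference lncRNAs are
   exempt), length >= 200 nt, at least one read observed;
2. class-code filter — gffcompare codes ``i`` (intronic), ``u``
   (intergenic) and ``x`` (antisense) define novel candidates, while
   ``=`` matches to reference transcripts annotated with biotype
   ``lncRNA`` are kept as known lncRNAs;
3. coding-potential consensus — a transcript is accepted as noncoding
   only if *all* enabled predictors call it noncoding (the intersection
   of predictor-specific Venn sets).

The external tools commonly used for step 3 (PLEK, CPAT, CNCI, CPC2) are
not executed; built-in scorers provide equivalent signals — longest-ORF
length, the Fickett TESTCODE statistic, an in-frame hexamer usage
log-ratio, and a logistic composite — and optional externally computed
score tables are honored in the consensus.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import AnnotationBundle, TranscriptModel

log = logging.getLogger("lncmast")

STOP_CODONS = ("TAA", "TAG", "TGA")
CLASS_CATEGORY = {"u": "lincRNA", "i": "ilncRNA", "x": "lncNAT"}


# ---------------------------------------------------------------------------
# ORF finding
# ---------------------------------------------------------------------------

def longest_orf(seq: str) -> tuple[int, int]:
    """Longest forward-frame ATG-to-stop ORF.

    Returns ``(start, length)`` with 0-based ``start`` and ``length`` in nt
    including the stop codon; ``(-1, 0)`` if the sequence has no complete
    ORF.  Transcript sequences are already oriented, so only the three
    forward frames are scanned.  Ties are broken toward the 5'-most start.
    """
    seq = seq.upper().replace("U", "T")
    best_start, best_len = -1, 0
    n = len(seq)
    for frame in range(3):
        open_start = -1  # earliest ATG since the last stop in this frame
        for pos in range(frame, n - 2, 3):
            codon = seq[pos:pos + 3]
            if codon in STOP_CODONS:
                if open_start >= 0:
                    length = pos + 3 - open_start
                    if length > best_len or (
                        length == best_len and open_start < best_start
                    ):
                        best_start, best_len = open_start, length
                    open_start = -1
            elif codon == "ATG" and open_start < 0:
                open_start = pos
    return best_start, best_len


# ---------------------------------------------------------------------------
# Fickett TESTCODE statistic
# ---------------------------------------------------------------------------
# Published lookup tables: probabilities that a sequence with a given
# position asymmetry / composition value is coding, and the weights of the
# eight parameters.

_POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_CUTS = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]

_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_CUTS = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]


def _lookup(value: float, cuts: list[float], probs: list[float]) -> float:
    for cut, prob in zip(cuts, probs):
        if value >= cut:
            return prob
    return probs[-1]


def fickett_score(seq: str) -> float:
    """TESTCODE statistic: weighted sum of eight composition/position
    parameters mapped through the published probability lookup tables.
    Values near or above ~0.95 indicate coding-like periodicity."""
    seq = seq.upper().replace("U", "T")
    if not seq:
        return 0.0
    score = 0.0
    for base in "ACGT":
        counts = [seq[i::3].count(base) for i in range(3)]
        position_value = max(counts) / (min(counts) + 1)
        content_value = sum(counts) / len(seq)
        score += _lookup(position_value, _POSITION_CUTS,
                         _POSITION_PROB[base]) * _POSITION_WEIGHT[base]
        score += _lookup(content_value, _CONTENT_CUTS,
                         _CONTENT_PROB[base]) * _CONTENT_WEIGHT[base]
    return score


# ---------------------------------------------------------------------------
# Hexamer usage
# ---------------------------------------------------------------------------

def train_hexamer_table(sequences, step: int = 1,
                        pseudocount: float = 1.0) -> dict[str, float]:
    """Hexamer frequency table from a set of training sequences.

    All 4096 ACGT hexamers get a pseudocount so log-ratios stay finite.
    """
    from itertools import product

    counts = {"".join(p): pseudocount for p in product("ACGT", repeat=6)}
    for seq in sequences:
        seq = seq.upper().replace("U", "T")
        for i in range(0, len(seq) - 5, step):
            hx = seq[i:i + 6]
            if hx in counts:
                counts[hx] += 1
    total = sum(counts.values())
    return {hx: c / total for hx, c in counts.items()}


def default_hexamer_tables() -> dict[str, dict[str, float]]:
    """Analytic default tables: a codon-usage product model for coding
    sequence (stop codons excluded) versus an AT-rich i.i.d. model for
    noncoding sequence.  Used when no trained tables are supplied."""
    from itertools import product

    coding_base = {"A": 0.22, "C": 0.28, "G": 0.28, "T": 0.22}
    noncoding_base = {"A": 0.31, "C": 0.19, "G": 0.19, "T": 0.31}
    codon_freq = {}
    for p in product("ACGT", repeat=3):
        codon = "".join(p)
        codon_freq[codon] = 0.0 if codon in STOP_CODONS else math.prod(
            coding_base[b] for b in codon
        )
    z = sum(codon_freq.values())
    codon_freq = {c: f / z for c, f in codon_freq.items()}
    eps = 1e-9
    coding = {}
    noncoding = {}
    for p in product("ACGT", repeat=6):
        hx = "".join(p)
        coding[hx] = codon_freq[hx[:3]] * codon_freq[hx[3:]] + eps
        noncoding[hx] = math.prod(noncoding_base[b] for b in hx) + eps
    return {"coding": coding, "noncoding": noncoding}


def hexamer_score(seq: str, tables: dict[str, dict[str, float]]) -> float:
    """Mean log2(f_coding / f_noncoding) over the in-frame hexamers of the
    longest ORF; 0.0 when the sequence has no complete ORF."""
    seq = seq.upper().replace("U", "T")
    start, length = longest_orf(seq)
    if length == 0:
        return 0.0
    coding, noncoding = tables["coding"], tables["noncoding"]
    ratios = []
    for pos in range(start, start + length - 5, 3):
        hx = seq[pos:pos + 6]
        if hx in coding:
            ratios.append(math.log2(coding[hx] / noncoding[hx]))
    return float(np.mean(ratios)) if ratios else 0.0


# ---------------------------------------------------------------------------
# Composite score and consensus
# ---------------------------------------------------------------------------

# logistic weights; calibrated so the composite crosses 0.5 exactly at the
# individual-predictor boundary point (ORF 300 nt, Fickett 0.95, hexamer 0)
_W_ORF = 1.0 / 150.0
_W_FICKETT = 4.0
_W_HEXAMER = 1.5
_B_COMPOSITE = -(_W_ORF * 300.0 + _W_FICKETT * 0.95)


@dataclass
class CodingThresholds:
    """Noncoding calls require: orf_length < orf, fickett < fickett,
    hexamer < hexamer, composite < composite (all strict)."""

    orf: float = 300.0
    fickett: float = 0.95
    hexamer: float = 0.0
    composite: float = 0.5


@dataclass
class CodingPotentialScores:
    transcript_id: str
    orf_length: int
    fickett: float
    hexamer: float
    composite: float
    external: dict[str, str] = field(default_factory=dict)
    call: str = "coding"


def score_coding_potential(
    sequences: dict[str, str],
    hexamer_tables: dict[str, dict[str, float]] | None = None,
) -> dict[str, CodingPotentialScores]:
    """Score every sequence with the built-in coding-potential predictors.

    Raises on non-ACGTN characters; sequences with more than 10% N are
    scored but flagged with a warning.
    """
    if hexamer_tables is None:
        hexamer_tables = default_hexamer_tables()
    out = {}
    for tid, seq in sequences.items():
        up = seq.upper().replace("U", "T")
        bad = set(up) - set("ACGTN")
        if bad:
            raise ValueError(
                f"transcript {tid}: non-ACGTN characters {sorted(bad)}"
            )
        if up and up.count("N") / len(up) > 0.1:
            log.warning("transcript %s: N fraction > 0.1, scores unreliable", tid)
        _, orf_len = longest_orf(up)
        fick = fickett_score(up)
        hexa = hexamer_score(up, hexamer_tables)
        logit = _W_ORF * orf_len + _W_FICKETT * fick + _W_HEXAMER * hexa + _B_COMPOSITE
        composite = 1.0 / (1.0 + math.exp(-logit))
        out[tid] = CodingPotentialScores(tid, orf_len, fick, hexa, composite)
    return out


def consensus_call(
    scores: dict[str, CodingPotentialScores],
    thresholds: CodingThresholds | None = None,
    external: dict[str, dict[str, str]] | None = None,
) -> set[str]:
    """Four-way-intersection consensus: noncoding iff every enabled internal
    predictor and every supplied external predictor calls noncoding.

    ``external`` maps predictor name -> {transcript_id -> "coding"|"noncoding"};
    a transcript missing from an external table is treated as coding
    (conservative) with a warning.  Sets ``scores[tid].call`` as a side
    effect and returns the noncoding transcript-id set.
    """
    thr = thresholds or CodingThresholds()
    external = external or {}
    noncoding: set[str] = set()
    for tid, s in scores.items():
        # a transcript with no complete ORF has hexamer score 0 by
        # definition; the absence of an ORF is noncoding evidence, not
        # coding evidence, so the hexamer criterion is waived there
        ok = (
            s.orf_length < thr.orf
            and s.fickett < thr.fickett
            and (s.orf_length == 0 or s.hexamer < thr.hexamer)
            and s.composite < thr.composite
        )
        for predictor, calls in external.items():
            if tid not in calls:
                log.warning(
                    "transcript %s missing from external table %s; "
                    "treated as coding", tid, predictor,
                )
                ok = False
            else:
                s.external[predictor] = calls[tid]
                ok = ok and calls[tid] == "noncoding"
        s.call = "noncoding" if ok else "coding"
        if ok:
            noncoding.add(tid)
    return noncoding


# ---------------------------------------------------------------------------
# Filter cascade
# ---------------------------------------------------------------------------

def known_lnc_ids(transcripts: list[TranscriptModel],
                  reference: AnnotationBundle) -> set[str]:
    """Transcripts whose class code is '=' and whose matched reference
    transcript (via cmp_ref, else the shared gene) is annotated lncRNA."""
    out = set()
    for t in transcripts:
        if t.class_code != "=":
            continue
        biotype = None
        if t.cmp_ref is not None:
            biotype = reference.transcript_biotype.get(t.cmp_ref)
        if biotype is None:
            gene = reference.genes.get(t.gene_id)
            biotype = gene.biotype if gene else None
        if biotype == "lncRNA":
            out.add(t.transcript_id)
    return out


def basic_filter(
    transcripts: list[TranscriptModel],
    min_exons: int = 2,
    min_length: int = 200,
    min_count: int = 1,
    known_ids: set[str] | None = None,
) -> list[TranscriptModel]:
    """Structural filter: exon_count >= min_exons, length >= min_length and
    max per-sample read count >= min_count.

    Transcripts already matched to reference lncRNAs (``known_ids``) bypass
    the exon-number criterion only — single-exon known lncRNAs survive, as
    single-exon annotated lncRNAs do in cattle.
    """
    known_ids = known_ids or set()
    kept = []
    for t in transcripts:
        exon_ok = t.exon_count >= min_exons or t.transcript_id in known_ids
        count_ok = t.counts is not None and int(np.max(t.counts)) >= min_count
        if exon_ok and t.length >= min_length and count_ok:
            kept.append(t)
    return kept


def class_code_filter(
    transcripts: list[TranscriptModel],
    reference: AnnotationBundle,
    allowed: frozenset[str] = frozenset({"i", "u", "x"}),
) -> tuple[list[TranscriptModel], list[TranscriptModel], list[TranscriptModel]]:
    """Partition transcripts by gffcompare class code.

    Returns ``(novel_candidates, known_lncRNAs, discarded)``.  Codes in
    ``allowed`` become novel candidates; ``=`` matches are routed through the
    reference-biotype check; anything else is discarded with a logged reason.
    """
    known = known_lnc_ids(transcripts, reference)
    novel, known_lnc, discarded = [], [], []
    discard_reasons: dict[str, int] = {}
    for t in transcripts:
        if t.class_code in allowed:
            novel.append(t)
        elif t.transcript_id in known:
            known_lnc.append(t)
        else:
            discarded.append(t)
            discard_reasons[t.class_code] = discard_reasons.get(t.class_code, 0) + 1
    for code, n in sorted(discard_reasons.items()):
        log.info("class_code_filter: discarded %d transcripts with code %r", n, code)
    return novel, known_lnc, discarded


@dataclass
class LncRNARecord:
    transcript: TranscriptModel
    category: str  # lincRNA | ilncRNA | lncNAT | known
    novel: bool

    @property
    def transcript_id(self) -> str:
        return self.transcript.transcript_id


def classify(
    novel_candidates: list[TranscriptModel],
    known_lnc: list[TranscriptModel],
) -> list[LncRNARecord]:
    """Assign catalog categories: u -> lincRNA, i -> ilncRNA, x -> lncNAT,
    reference-matched -> known.  Every entry gets exactly one category."""
    records = [
        LncRNARecord(t, CLASS_CATEGORY[t.class_code], novel=True)
        for t in novel_candidates
        if t.class_code in CLASS_CATEGORY
    ]
    records += [LncRNARecord(t, "known", novel=False) for t in known_lnc]
    return records


def identify_lncrnas(
    assembly: AnnotationBundle,
    reference: AnnotationBundle,
    sequences: dict[str, str],
    hexamer_tables: dict[str, dict[str, float]] | None = None,
    thresholds: CodingThresholds | None = None,
    external: dict[str, dict[str, str]] | None = None,
    min_exons: int = 2,
    min_length: int = 200,
    min_count: int = 1,
) -> tuple[list[LncRNARecord], dict[str, CodingPotentialScores]]:
    """Full identification cascade; returns the lncRNA catalog and the
    coding-potential scores of every consensus-screened candidate."""
    known = known_lnc_ids(assembly.transcripts, reference)
    surv = basic_filter(assembly.transcripts, min_exons, min_length,
                        min_count, known_ids=known)
    novel_cand, known_lnc, _ = class_code_filter(surv, reference)
    candidates = novel_cand + known_lnc
    seqs = {}
    for t in candidates:
        if t.transcript_id not in sequences:
            log.warning("no sequence for %s; dropped from catalog", t.transcript_id)
            continue
        seqs[t.transcript_id] = sequences[t.transcript_id]
    scores = score_coding_potential(seqs, hexamer_tables)
    noncoding = consensus_call(scores, thresholds, external)
    novel_pass = [t for t in novel_cand if t.transcript_id in noncoding]
    known_pass = [t for t in known_lnc if t.transcript_id in noncoding]
    return classify(novel_pass, known_pass), scores


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def catalog_table(catalog: list[LncRNARecord]) -> pd.DataFrame:
    rows = [
        {
            "transcript_id": r.transcript_id,
            "gene_id": r.transcript.gene_id,
            "chrom": r.transcript.chrom,
            "class_code": r.transcript.class_code,
            "category": r.category,
            "novel": r.novel,
            "length": r.transcript.length,
            "exons": r.transcript.exon_count,
        }
        for r in catalog
    ]
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "gene_id", "chrom", "class_code",
                 "category", "novel", "length", "exons"],
    ).sort_values("transcript_id", ignore_index=True)


def feature_report(catalog: list[LncRNARecord]) -> dict[str, pd.DataFrame]:
    """Summary tables of the catalog: exon-count histogram, length bins
    ([200, 1500] and >1500 nt), per-chromosome counts, novel/known split.
    Every histogram sums to the catalog size; empty catalog gives empty
    tables."""
    if not catalog:
        return {
            "exon_hist": pd.DataFrame(columns=["exons", "count"]),
            "length_bins": pd.DataFrame(columns=["bin", "count"]),
            "chrom_counts": pd.DataFrame(columns=["chrom", "count"]),
            "category_counts": pd.DataFrame(columns=["category", "count"]),
        }
    df = catalog_table(catalog)
    exon_hist = (
        df["exons"].value_counts().sort_index().rename_axis("exons")
        .reset_index(name="count")
    )
    bins = pd.cut(df["length"], [200 - 1, 1500, np.inf],
                  labels=["200-1500", ">1500"])
    length_bins = (
        bins.value_counts().sort_index().rename_axis("bin")
        .reset_index(name="count")
    )
    chrom_counts = (
        df["chrom"].value_counts().sort_index().rename_axis("chrom")
        .reset_index(name="count")
    )
    category_counts = (
        df["category"].value_counts().sort_index().rename_axis("category")
        .reset_index(name="count")
    )
    return {
        "exon_hist": exon_hist,
        "length_bins": length_bins,
        "chrom_counts": chrom_counts,
        "category_counts": category_counts,
    }
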