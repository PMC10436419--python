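"""Ground-truthed synthetic inputs for the whole pipeline.

Emulates the statistical structure every downstream stage assumes, at a
scale where the full analysis runs in seconds:

* a small genome (3 chromosomes x 5 Mb by default) with ~300 protein-coding
  genes, novel lncRNAs of the three assembly classes (intergenic ``u``,
  intronic ``i``, antisense ``x``) and reference-annotated known lncRNAs
  (``=``), plus a sprinkle of deliberate filter violators (single exon,
  < 200 nt, zero counts, coding-like sequence) so the identification
  cascade has work to do;
* transcript sequences in which coding transcripts carry a long embedded
  ORF with biased codon usage while noncoding transcripts are AT-rich with
  only short spurious ORFs;
* negative-binomial read counts over 14 samples (4 SF, 4 SC, 3 HF, 3 HC)
  with >= 2-fold library-size variation, planted fold changes, planted
  co-expression modules tied to group membership, a log-normal somatic
  cell count phenotype (high in the subclinical-mastitis groups) with
  SCC-linked genes, and strongly co-varying lncRNA-mRNA pairs for the
  trans-target screen;
* QTL intervals planted within the +/-100 kb window of chosen DE lncRNAs
  (plus decoys outside it) and GWAS SNPs with uniform p-values except for
  an inflated chi-square signal near a chosen gene set.

Every generated feature is recorded in a :class:`GroundTruth` object, so
sensitivity and specificity of each stage can be scored without any real
data.  All generation is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import (AnnotationBundle, GeneRecord, SampleMeta,
                         TranscriptModel, write_fasta, write_gtf)
from .lncrna_identify import STOP_CODONS, longest_orf

log = logging.getLogger("lncmast")

CODING_BASE = {"A": 0.22, "C": 0.28, "G": 0.28, "T": 0.22}
NONCODING_BASE = {"A": 0.33, "C": 0.17, "G": 0.17, "T": 0.33}
VIOLATION_TYPES = ("one_exon", "short", "zero_count", "coding_like")


@dataclass
class SyntheticConfig:
    """The stated world: genome size, cohort layout, planted effects."""

    n_chroms: int = 3
    chrom_len: int = 5_000_000
    n_coding_genes: int = 300
    # novel intergenic (u), intronic (i), antisense (x), known (=)
    n_lnc_per_class: tuple[int, int, int, int] = (40, 15, 40, 25)
    n_decoys: int = 10
    violator_fraction: float = 0.15
    window: int = 100_000
    # counts
    group_sizes: tuple[int, int, int, int] = (4, 4, 3, 3)  # SF, SC, HF, HC
    n_de_mrna: int = 30  # per comparison
    n_de_lnc: int = 12
    n_shared_mrna: int = 5
    n_shared_lnc: int = 2
    effect_range: tuple[float, float] = (2.0, 3.0)
    module_sizes: tuple[int, ...] = (50, 50, 50)
    n_scc_genes: int = 6
    n_trans_pairs: int = 6
    dispersion_median: float = 0.1
    scc_median_s: float = 600.0  # x1000 cells/mL, subclinical mastitis groups
    scc_median_h: float = 100.0
    # qtl / gwas
    n_qtl_hits: int = 8
    n_qtl_decoys: int = 10
    n_snps_per_trait: int = 1500
    n_gwas_genes: int = 12
    ext: int = 50_000
    gwas_traits: tuple[str, ...] = ("Mastitis", "Somatic cell score",
                                    "Milk protein")
    gwas_inflated_trait: str = "Somatic cell score"


@dataclass
class GroundTruth:
    """Everything planted, sufficient to score every downstream stage."""

    true_lncRNAs: dict[str, str] = field(default_factory=dict)  # tid -> category
    violators: dict[str, str] = field(default_factory=dict)  # tid -> violation
    coding_genes: list[str] = field(default_factory=list)
    lnc_transcripts: list[str] = field(default_factory=list)
    decoys: list[str] = field(default_factory=list)
    planted_DE: dict[str, dict[str, float]] = field(default_factory=dict)
    planted_modules: dict[str, dict] = field(default_factory=dict)
    planted_scc_genes: list[str] = field(default_factory=list)
    planted_targets: list[tuple[str, str, str]] = field(default_factory=list)
    planted_qtl_hits: list[tuple[str, str]] = field(default_factory=list)
    decoy_qtl_ids: list[str] = field(default_factory=list)
    planted_gwas_genes: list[str] = field(default_factory=list)
    planted_gwas_trait: str = ""
    library_factors: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        gt = cls(**raw)
        gt.planted_targets = [tuple(t) for t in gt.planted_targets]
        gt.planted_qtl_hits = [tuple(t) for t in gt.planted_qtl_hits]
        return gt


def make_samples(seed: int, config: SyntheticConfig | None = None) -> list[SampleMeta]:
    """Cohort metadata: group labels and log-normal SCC, high in the
    subclinical-mastitis (S) groups, low in the healthy (H) groups."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng([seed, 101])
    samples = []
    for group, n in zip(("SF", "SC", "HF", "HC"), cfg.group_sizes):
        median = cfg.scc_median_s if group[0] == "S" else cfg.scc_median_h
        for i in range(n):
            scc = float(np.exp(np.log(median) + 0.35 * rng.standard_normal()))
            samples.append(SampleMeta(f"{group}{i + 1}", group, round(scc, 1)))
    return samples


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def _make_exons(rng, start: int, n_exons: int, exon_len: tuple[int, int],
                intron_len: tuple[int, int]) -> list[tuple[int, int]]:
    exons = []
    pos = start
    for i in range(n_exons):
        length = int(rng.integers(exon_len[0], exon_len[1] + 1))
        exons.append((pos, pos + length - 1))
        pos += length + int(rng.integers(intron_len[0], intron_len[1] + 1))
    return exons


def _exons_for_length(rng, start: int, total_len: int, n_exons: int,
                      intron_len: tuple[int, int]) -> list[tuple[int, int]]:
    """Exons with the given exact total length."""
    if n_exons == 1:
        return [(start, start + total_len - 1)]
    cuts = np.sort(rng.choice(np.arange(1, total_len), size=n_exons - 1,
                              replace=False))
    lens = np.diff(np.concatenate(([0], cuts, [total_len])))
    exons = []
    pos = start
    for length in lens:
        exons.append((pos, pos + int(length) - 1))
        pos += int(length) + int(rng.integers(intron_len[0], intron_len[1] + 1))
    return exons


def generate_annotation(
    seed: int, config: SyntheticConfig | None = None,
) -> tuple[AnnotationBundle, AnnotationBundle, GroundTruth]:
    """Build the reference and assembly annotations plus the ground truth.

    Layout per chromosome: a gene-dense zone, an intergenic desert at least
    ``window`` bp beyond any gene (where class-u lncRNAs go), and a distal
    zone holding the reference-annotated known lncRNA genes.  Class-i
    lncRNAs sit strictly inside a host intron; class-x lncRNAs overlap a
    coding exon on the opposite strand.  A configured fraction of noncoding
    transcripts deliberately violates one identification filter.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng([seed, 11])
    truth = GroundTruth()
    reference = AnnotationBundle()
    assembly = AnnotationBundle()
    L = cfg.chrom_len
    gene_zone_end = int(0.55 * L)
    u_zone = (gene_zone_end + cfg.window + 10_000, int(0.93 * L) - cfg.window)
    known_zone = (int(0.93 * L) + 10_000, L - 10_000)
    if u_zone[1] - u_zone[0] < 200_000:
        raise ValueError("generate_annotation: chromosome too short for the "
                         "requested layout; increase chrom_len")

    chroms = [str(c + 1) for c in range(cfg.n_chroms)]
    mstrg = iter(range(1, 10_000))

    # --- coding genes, one transcript each -------------------------------
    per_chrom = int(np.ceil(cfg.n_coding_genes / cfg.n_chroms))
    coding_tx: list[TranscriptModel] = []
    g = 0
    for chrom in chroms:
        spacing = (gene_zone_end - 20_000) // per_chrom
        for i in range(per_chrom):
            if g >= cfg.n_coding_genes:
                break
            gid = f"G{g + 1:04d}"
            start = 10_000 + i * spacing + int(rng.integers(0, 2000))
            exons = _make_exons(rng, start, int(rng.integers(3, 7)),
                                (150, 400), (1000, 3000))
            strand = str(rng.choice(["+", "-"]))
            tx = TranscriptModel(f"{gid}.t1", gid, chrom, strand, exons,
                                 class_code="unknown")
            reference.transcripts.append(tx)
            reference.genes[gid] = GeneRecord(gid, chrom, exons[0][0],
                                              exons[-1][1], strand,
                                              "protein_coding")
            reference.transcript_biotype[f"{gid}.t1"] = "protein_coding"
            coding_tx.append(tx)
            # the assembly recovers the reference transcript exactly
            assembly.transcripts.append(TranscriptModel(
                f"MSTRG.{next(mstrg)}.1", gid, chrom, strand, list(exons),
                class_code="=", cmp_ref=f"{gid}.t1",
            ))
            truth.coding_genes.append(gid)
            g += 1

    n_u, n_i, n_x, n_known = cfg.n_lnc_per_class
    lnc_new: list[tuple[TranscriptModel, str]] = []  # (transcript, category)

    # --- class u: intergenic desert --------------------------------------
    for j in range(n_u):
        chrom = chroms[j % cfg.n_chroms]
        zone_len = u_zone[1] - u_zone[0]
        spacing = zone_len // max(1, int(np.ceil(n_u / cfg.n_chroms)))
        start = u_zone[0] + (j // cfg.n_chroms) * spacing + int(rng.integers(0, 500))
        total = int(rng.integers(300, 1800))
        exons = _exons_for_length(rng, start, total, int(rng.integers(2, 5)),
                                  (100, 800))
        tx = TranscriptModel(f"MSTRG.{next(mstrg)}.1", f"MSTRG.{j + 20000}",
                             chrom, str(rng.choice(["+", "-"])), exons,
                             class_code="u")
        lnc_new.append((tx, "lincRNA"))

    # --- class i: strictly inside a host intron ---------------------------
    hosts = [t for t in coding_tx if any(
        e - s + 1 >= 2200 for s, e in t.introns())]
    for j in range(n_i):
        host = hosts[int(rng.integers(0, len(hosts)))]
        intr = [iv for iv in host.introns() if iv[1] - iv[0] + 1 >= 2200]
        istart, iend = intr[int(rng.integers(0, len(intr)))]
        total = int(rng.integers(250, min(1200, iend - istart - 600)))
        start = istart + 1 + int(rng.integers(0, iend - istart - total - 500))
        exons = _exons_for_length(rng, start, total, 2, (50, 120))
        while exons[-1][1] >= iend:  # keep strictly inside the intron
            exons = _exons_for_length(rng, start, total, 2, (50, 80))
        tx = TranscriptModel(f"MSTRG.{next(mstrg)}.1", f"MSTRG.{j + 21000}",
                             host.chrom, str(rng.choice(["+", "-"])), exons,
                             class_code="i")
        lnc_new.append((tx, "ilncRNA"))

    # --- class x: antisense overlap of a coding exon ----------------------
    for j in range(n_x):
        host = coding_tx[int(rng.integers(0, len(coding_tx)))]
        es, ee = host.exons[int(rng.integers(0, host.exon_count))]
        first_len = (ee - es + 1) + int(rng.integers(100, 400))
        start = max(1, es - int(rng.integers(50, 200)))
        exons = [(start, start + first_len - 1)]
        pos = exons[0][1] + 1 + int(rng.integers(200, 800))
        exons.append((pos, pos + int(rng.integers(150, 500))))
        strand = "-" if host.strand == "+" else "+"
        tx = TranscriptModel(f"MSTRG.{next(mstrg)}.1", f"MSTRG.{j + 22000}",
                             host.chrom, strand, exons, class_code="x")
        lnc_new.append((tx, "lncNAT"))

    # --- known lncRNAs ('=' to reference lncRNA biotype) ------------------
    for j in range(n_known):
        chrom = chroms[j % cfg.n_chroms]
        spacing = (known_zone[1] - known_zone[0]) // max(
            1, int(np.ceil(n_known / cfg.n_chroms)))
        start = known_zone[0] + (j // cfg.n_chroms) * spacing + int(
            rng.integers(0, 500))
        n_ex = 1 if j % 5 == 0 else int(rng.integers(2, 4))
        total = int(rng.integers(300, 1500))
        exons = _exons_for_length(rng, start, total, n_ex, (100, 500))
        gid = f"LNC{j + 1:03d}"
        strand = str(rng.choice(["+", "-"]))
        ref_tx = TranscriptModel(f"{gid}.t1", gid, chrom, strand, exons)
        reference.transcripts.append(ref_tx)
        reference.genes[gid] = GeneRecord(gid, chrom, exons[0][0],
                                          exons[-1][1], strand, "lncRNA")
        reference.transcript_biotype[f"{gid}.t1"] = "lncRNA"
        tx = TranscriptModel(f"MSTRG.{next(mstrg)}.1", gid, chrom, strand,
                             list(exons), class_code="=", cmp_ref=f"{gid}.t1")
        lnc_new.append((tx, "known"))

    # --- planted filter violators (novel classes only) --------------------
    novel_idx = [i for i, (_, cat) in enumerate(lnc_new) if cat != "known"]
    n_viol = int(round(cfg.violator_fraction * len(lnc_new)))
    viol_idx = rng.choice(novel_idx, size=min(n_viol, len(novel_idx)),
                          replace=False)
    for v, idx in enumerate(np.sort(viol_idx)):
        tx, _cat = lnc_new[idx]
        vtype = VIOLATION_TYPES[v % len(VIOLATION_TYPES)]
        if vtype == "one_exon":
            s = tx.exons[0][0]
            tx.exons = [(s, s + tx.length - 1)]
            if tx.class_code == "i":  # keep the intron-containment property
                tx.exons = [(tx.exons[0][0],
                             min(tx.exons[0][1], tx.exons[0][0] + 400))]
        elif vtype == "short":
            s = tx.exons[0][0]
            half = int(rng.integers(60, 90))
            tx.exons = [(s, s + half - 1),
                        (s + half + 100, s + half + 100 + (170 - half) - 1)]
        truth.violators[tx.transcript_id] = vtype

    for tx, cat in lnc_new:
        assembly.transcripts.append(tx)
        truth.lnc_transcripts.append(tx.transcript_id)
        if tx.transcript_id not in truth.violators:
            truth.true_lncRNAs[tx.transcript_id] = cat

    # --- decoy assembly artifacts (other class codes) ---------------------
    for j in range(cfg.n_decoys):
        host = coding_tx[int(rng.integers(0, len(coding_tx)))]
        exons = [(s + 20, e - 20) for s, e in host.exons[:2]]
        tx = TranscriptModel(f"MSTRG.{next(mstrg)}.1", host.gene_id,
                             host.chrom, host.strand, exons,
                             class_code=str(rng.choice(["j", "o", "e"])))
        assembly.transcripts.append(tx)
        truth.decoys.append(tx.transcript_id)

    # planted cis targets: coding genes within the window of a true lncRNA
    for tx, _cat in lnc_new:
        if tx.transcript_id not in truth.true_lncRNAs:
            continue
        for gid, gene in reference.genes.items():
            if gene.biotype != "protein_coding" or gene.chrom != tx.chrom:
                continue
            gap = max(0, max(tx.start, gene.start) - min(tx.end, gene.end))
            if gap <= cfg.window:
                truth.planted_targets.append((tx.transcript_id, gid, "cis"))
    return assembly, reference, truth


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def _random_seq(rng, length: int, base_probs: dict[str, float]) -> str:
    bases = np.array(list("ACGT"))
    probs = np.array([base_probs[b] for b in "ACGT"])
    return "".join(rng.choice(bases, size=length, p=probs))


def _coding_seq(rng, length: int) -> str:
    """UTR + (ATG + biased codons + stop) + UTR; ORF covers ~70% of the
    transcript and is at least 300 nt whenever the length allows."""
    orf_len = max(300, 3 * int(0.7 * length / 3))
    orf_len = min(orf_len, 3 * ((length - 30) // 3))
    n_codons = orf_len // 3 - 2  # minus start and stop
    codons = []
    bases = np.array(list("ACGT"))
    probs = np.array([CODING_BASE[b] for b in "ACGT"])
    while len(codons) < n_codons:
        c = "".join(rng.choice(bases, size=3, p=probs))
        if c not in STOP_CODONS:
            codons.append(c)
    orf = "ATG" + "".join(codons) + str(rng.choice(list(STOP_CODONS)))
    utr_total = length - len(orf)
    u5 = int(rng.integers(0, utr_total + 1))
    return (_random_seq(rng, u5, NONCODING_BASE) + orf
            + _random_seq(rng, utr_total - u5, NONCODING_BASE))


def _break_orfs(rng, seq: str, max_orf: int = 140) -> str:
    """Interrupt every ORF of >= max_orf nt with a stop codon so the
    noncoding sequence carries only short spurious ORFs."""
    seq = list(seq)
    while True:
        start, length = longest_orf("".join(seq))
        if length < max_orf:
            return "".join(seq)
        mid = start + 3 * (length // 6)
        seq[mid:mid + 3] = list(rng.choice(list(STOP_CODONS)))


def generate_sequences(
    assembly: AnnotationBundle,
    truth: GroundTruth,
    seed: int,
) -> dict[str, str]:
    """Sequence for every assembly transcript, keyed by transcript id.

    Coding transcripts (and coding-like violators and decoys) embed a long
    ORF drawn from the biased codon model; everything else is AT-rich with
    ORFs broken below 140 nt.  Sequence length equals the annotated
    transcript length; GC stays within [0.3, 0.7] by construction.
    """
    rng = np.random.default_rng([seed, 22])
    coding_like = set(truth.decoys) | {
        tid for tid, v in truth.violators.items() if v == "coding_like"
    }
    coding_gene_set = set(truth.coding_genes)
    seqs: dict[str, str] = {}
    for t in sorted(assembly.transcripts, key=lambda t: t.transcript_id):
        n = t.length
        # short sequences can drift outside the GC band by sampling noise;
        # redraw until they land inside it
        for _attempt in range(100):
            if t.gene_id in coding_gene_set or t.transcript_id in coding_like:
                seq = _coding_seq(rng, n) if n >= 400 else _random_seq(
                    rng, n, CODING_BASE)
            else:
                seq = _break_orfs(rng, _random_seq(rng, n, NONCODING_BASE))
            gc = (seq.count("G") + seq.count("C")) / max(1, len(seq))
            if 0.3 <= gc <= 0.7:
                break
        else:
            raise RuntimeError(f"could not draw GC-bounded sequence for "
                               f"{t.transcript_id}")
        seqs[t.transcript_id] = seq
    return seqs


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def _nb_draw(rng, mu: np.ndarray, alpha: float) -> np.ndarray:
    if alpha < 1e-8:
        return rng.poisson(mu)
    n_param = 1.0 / alpha
    p = n_param / (n_param + mu)
    return rng.negative_binomial(n_param, p)


def generate_counts(
    assembly: AnnotationBundle,
    truth: GroundTruth,
    samples: list[SampleMeta],
    seed: int,
    config: SyntheticConfig | None = None,
    de_config: dict[str, dict[str, float]] | None = None,
) -> pd.DataFrame:
    """Negative-binomial count matrix (features x samples) with planted
    structure; updates ``truth`` in place.

    Features are coding gene ids plus noncoding/decoy transcript ids.
    ``de_config`` may pre-specify comparison -> {feature -> signed log2
    effect}; by default effects are drawn per the configuration.  Planted
    co-expression modules share a latent factor tied to group membership;
    SCC-linked genes scale log-linearly with the SCC phenotype; planted
    trans-target pairs additionally share a strong per-sample factor.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng([seed, 33])
    groups = pd.Series({s.sample_id: s.group for s in samples})
    for grp in ("SF", "SC", "HF", "HC"):
        if (groups == grp).sum() < 2:
            raise ValueError(f"generate_counts: fewer than 2 samples in {grp}")
    scc = np.array([s.scc for s in samples], dtype=float)
    features = list(truth.coding_genes) + list(truth.lnc_transcripts) + list(
        truth.decoys)
    nf, ns = len(features), len(samples)
    fidx = {f: i for i, f in enumerate(features)}

    mu = np.empty(nf)
    n_cod = len(truth.coding_genes)
    mu[:n_cod] = np.clip(np.exp(np.log(200) + rng.standard_normal(n_cod)),
                         20, 4000)
    mu[n_cod:] = np.clip(np.exp(np.log(100) + 0.8 * rng.standard_normal(
        nf - n_cod)), 20, 1500)
    for tid, v in truth.violators.items():
        if v == "zero_count":
            mu[fidx[tid]] = 0.0
    alpha = np.exp(np.log(cfg.dispersion_median)
                   + 0.5 * rng.standard_normal(nf))

    # per-sample log2 mean offsets accumulate planted structure
    log2_shift = np.zeros((nf, ns))
    is_group = {g: (groups.values == g) for g in ("SF", "SC", "HF", "HC")}

    # --- planted differential expression ----------------------------------
    if de_config is None:
        de_config = {}
        true_lnc = [t for t in truth.true_lncRNAs]
        shared_m = list(rng.choice(truth.coding_genes, cfg.n_shared_mrna,
                                   replace=False))
        shared_l = list(rng.choice(true_lnc, cfg.n_shared_lnc, replace=False))
        used = set(shared_m) | set(shared_l)
        for comp in ("SFvsSC", "HFvsHC"):
            pool_m = [g for g in truth.coding_genes if g not in used]
            pool_l = [t for t in true_lnc if t not in used]
            own_m = list(rng.choice(pool_m, cfg.n_de_mrna - cfg.n_shared_mrna,
                                    replace=False))
            own_l = list(rng.choice(pool_l, cfg.n_de_lnc - cfg.n_shared_lnc,
                                    replace=False))
            used |= set(own_m) | set(own_l)
            effects = {}
            for f in shared_m + shared_l + own_m + own_l:
                mag = rng.uniform(*cfg.effect_range)
                effects[f] = float(mag * rng.choice([-1.0, 1.0]))
            de_config[comp] = effects
    truth.planted_DE = {c: dict(e) for c, e in de_config.items()}

    for comp, effects in de_config.items():
        treat = {"SFvsSC": "SF", "HFvsHC": "HF"}[comp]
        for f, eff in effects.items():
            i = fidx[f]
            mu[i] = max(mu[i], 150.0)  # planted effects at decent depth
            log2_shift[i, is_group[treat]] += eff

    # --- planted co-expression modules ------------------------------------
    de_features = {f for e in de_config.values() for f in e}
    module_assoc = [("S_status", is_group["SF"] | is_group["SC"]),
                    ("F_status", is_group["SF"] | is_group["HF"]),
                    ("SF_only", is_group["SF"])]
    pool = [g for g in truth.coding_genes if g not in de_features
            and g not in truth.planted_scc_genes]
    for m, size in enumerate(cfg.module_sizes):
        name, indicator = module_assoc[m % len(module_assoc)]
        members = list(rng.choice(pool, size, replace=False))
        pool = [g for g in pool if g not in set(members)]
        z = indicator.astype(float)
        f_s = (z - z.mean()) + 0.4 * rng.standard_normal(ns)
        for gmember in members:
            i = fidx[gmember]
            lam = rng.uniform(1.0, 1.4)
            log2_shift[i] += lam * f_s
            mu[i] = max(mu[i], 200.0)
            alpha[i] = 0.02
        truth.planted_modules[f"M{m + 1}"] = {"genes": members,
                                              "association": name}

    # --- SCC-linked genes --------------------------------------------------
    scc_z = (scc - scc.mean()) / scc.std()
    scc_pool = [g for g in truth.coding_genes
                if g not in de_features
                and not any(g in mod["genes"]
                            for mod in truth.planted_modules.values())]
    scc_genes = list(rng.choice(scc_pool, cfg.n_scc_genes, replace=False))
    for gmember in scc_genes:
        i = fidx[gmember]
        log2_shift[i] += 1.2 * scc_z
        mu[i] = max(mu[i], 200.0)
        alpha[i] = 0.05
    truth.planted_scc_genes = scc_genes

    # --- planted trans-target pairs ----------------------------------------
    in_both = set(de_config.get("SFvsSC", {})) & set(de_config.get("HFvsHC", {}))
    lnc_de_s = [f for f in de_config.get("SFvsSC", {})
                if f in truth.true_lncRNAs and f not in in_both]
    mrna_de_s = [f for f in de_config.get("SFvsSC", {})
                 if f in set(truth.coding_genes) and f not in in_both]
    n_pairs = min(cfg.n_trans_pairs, len(lnc_de_s), len(mrna_de_s))
    for k in range(n_pairs):
        lnc, gene = lnc_de_s[k], mrna_de_s[k]
        il, ig = fidx[lnc], fidx[gene]
        # the lncRNA copies the gene's group effect, plus a shared factor
        de_config["SFvsSC"][lnc] = de_config["SFvsSC"][gene]
        log2_shift[il] = log2_shift[ig].copy()
        shared = 0.7 * rng.standard_normal(ns)
        log2_shift[il] += shared
        log2_shift[ig] += shared
        mu[il] = mu[ig] = 1500.0
        alpha[il] = alpha[ig] = 1e-4
        truth.planted_targets.append((lnc, gene, "trans"))
    truth.planted_DE = {c: dict(e) for c, e in de_config.items()}

    # --- library sizes and the draw ----------------------------------------
    lib = 2.0 ** np.linspace(-0.55, 0.55, ns)
    rng.shuffle(lib)
    truth.library_factors = {s.sample_id: float(lib[j])
                             for j, s in enumerate(samples)}
    counts = np.empty((nf, ns), dtype=np.int64)
    for i in range(nf):
        m = mu[i] * (2.0 ** log2_shift[i]) * lib
        counts[i] = _nb_draw(rng, m, float(alpha[i]))
    df = pd.DataFrame(counts, index=pd.Index(features, name="feature_id"),
                      columns=[s.sample_id for s in samples])

    # attach per-transcript read counts for the identification filters
    for t in assembly.transcripts:
        row = t.transcript_id if t.transcript_id in df.index else t.gene_id
        if row in df.index:
            t.counts = df.loc[row].values
    return df


# ---------------------------------------------------------------------------
# QTL and GWAS
# ---------------------------------------------------------------------------

def generate_qtl_gwas(
    assembly: AnnotationBundle,
    truth: GroundTruth,
    seed: int,
    config: SyntheticConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """QTL intervals and GWAS SNPs with planted structure; updates ``truth``.

    Planted QTLs sit within the +/-window of chosen DE lncRNAs; decoys are
    placed so that they are farther than the window from *every* DE lncRNA.
    GWAS p-values are Uniform(0, 1] except near the planted gene set for the
    inflated trait, where they follow an inflated chi-square signal.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng([seed, 44])
    tx_by_id = assembly.by_id()
    de_lnc = sorted({f for e in truth.planted_DE.values() for f in e
                     if f in truth.true_lncRNAs})
    if not de_lnc:
        raise ValueError("generate_qtl_gwas: no planted DE lncRNAs; "
                         "generate counts first")
    qtl_traits = ("Somatic cell score", "Somatic cell count",
                  "Clinical mastitis")
    rows = []
    qid = 40_000
    hits = de_lnc[: cfg.n_qtl_hits]
    for k, lnc in enumerate(hits):
        t = tx_by_id[lnc]
        gap = int(rng.integers(1_000, cfg.window - 5_000))
        if bool(rng.integers(0, 2)) and t.start - gap - 4 > 1:
            start = t.start - gap - 4
        else:
            start = t.end + gap
        rows.append({"chrom": t.chrom, "start": start, "end": start + 4,
                     "trait": qtl_traits[k % 3], "qtl_id": str(qid + k)})
        truth.planted_qtl_hits.append((lnc, str(qid + k)))

    de_spans = [(tx_by_id[l].chrom, tx_by_id[l].start, tx_by_id[l].end)
                for l in de_lnc]
    placed = 0
    attempts = 0
    while placed < cfg.n_qtl_decoys and attempts < 10_000:
        attempts += 1
        chrom = str(int(rng.integers(1, cfg.n_chroms + 1)))
        start = int(rng.integers(1, cfg.chrom_len - 10))
        end = start + 4
        ok = all(
            c != chrom or max(0, max(s, start) - min(e, end)) > cfg.window
            for c, s, e in de_spans
        )
        if ok:
            dq = str(qid + cfg.n_qtl_hits + placed)
            rows.append({"chrom": chrom, "start": start, "end": end,
                         "trait": qtl_traits[placed % 3], "qtl_id": dq})
            truth.decoy_qtl_ids.append(dq)
            placed += 1
    qtl = pd.DataFrame(rows, columns=["chrom", "start", "end", "trait",
                                      "qtl_id"])

    # --- GWAS SNPs ---------------------------------------------------------
    gene_spans = {}
    for t in assembly.transcripts:
        if t.gene_id in set(truth.coding_genes):
            gene_spans[t.gene_id] = (t.chrom, t.start, t.end)
    de_mrna = sorted({f for f in truth.planted_DE.get("SFvsSC", {})
                      if f in gene_spans})
    planted_genes = de_mrna[: cfg.n_gwas_genes]
    truth.planted_gwas_genes = planted_genes
    truth.planted_gwas_trait = cfg.gwas_inflated_trait

    snp_rows = []
    for trait in cfg.gwas_traits:
        chrom = rng.integers(1, cfg.n_chroms + 1, size=cfg.n_snps_per_trait)
        pos = rng.integers(1, cfg.chrom_len, size=cfg.n_snps_per_trait)
        pval = 1.0 - rng.random(cfg.n_snps_per_trait)  # Uniform(0, 1]
        for c, p, pv in zip(chrom, pos, pval):
            snp_rows.append({"chrom": str(c), "pos": int(p), "trait": trait,
                             "pvalue": float(pv)})
        if trait == cfg.gwas_inflated_trait:
            for gid in planted_genes:
                c, s, e = gene_spans[gid]
                for _ in range(8):
                    p = int(rng.integers(max(1, s - cfg.ext), e + cfg.ext))
                    z = rng.normal(4.5, 1.0)
                    pv = float(np.clip(stats.chi2.sf(z * z, df=1),
                                       1e-300, 1.0))
                    snp_rows.append({"chrom": c, "pos": p, "trait": trait,
                                     "pvalue": pv})
    gwas = pd.DataFrame(snp_rows, columns=["chrom", "pos", "trait", "pvalue"])
    return qtl, gwas


# ---------------------------------------------------------------------------
# Gene sets and the full bundle
# ---------------------------------------------------------------------------

def generate_gmt(truth: GroundTruth, seed: int, n_terms: int = 20,
                 term_size: tuple[int, int] = (10, 40)) -> dict:
    """GMT-style gene sets over the coding genes.  The first term is
    enriched for planted DE genes so over-representation has signal."""
    rng = np.random.default_rng([seed, 55])
    genes = list(truth.coding_genes)
    # seed the planted term from one comparison's DE genes so that the
    # term is genuinely over-represented in that comparison's study set
    source = truth.planted_DE.get("SFvsSC") or {
        f for e in truth.planted_DE.values() for f in e}
    de_genes = sorted(f for f in source if f in set(genes))
    gmt = {}
    members = set(de_genes[:15]) | set(
        rng.choice(genes, 10, replace=False))
    gmt["SET0001"] = ("immune response (planted)", frozenset(members))
    for i in range(1, n_terms):
        size = int(rng.integers(term_size[0], term_size[1]))
        gmt[f"SET{i + 1:04d}"] = (
            f"random set {i}", frozenset(rng.choice(genes, size, replace=False))
        )
    return gmt


def generate_all(seed: int, outdir: str | Path,
                 config: SyntheticConfig | None = None) -> dict:
    """Generate the complete synthetic input set and write every file the
    pipeline reads.  Returns a dict of paths plus the ground truth."""
    cfg = config or SyntheticConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    assembly, reference, truth = generate_annotation(seed, cfg)
    samples = make_samples(seed, cfg)
    counts = generate_counts(assembly, truth, samples, seed, cfg)
    seqs = generate_sequences(assembly, truth, seed)
    qtl, gwas = generate_qtl_gwas(assembly, truth, seed, cfg)
    gmt = generate_gmt(truth, seed)

    paths = {
        "assembly_gtf": outdir / "assembly.gtf",
        "reference_gtf": outdir / "reference.gtf",
        "fasta": outdir / "transcripts.fa",
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "qtl": outdir / "qtl.tsv",
        "gwas": outdir / "gwas.tsv",
        "gmt": outdir / "genesets.gmt",
        "truth": outdir / "ground_truth.json",
    }
    write_gtf(assembly, paths["assembly_gtf"], dialect="assembly")
    write_gtf(reference, paths["reference_gtf"], dialect="reference")
    write_fasta(seqs, paths["fasta"])
    counts.to_csv(paths["counts"], sep="\t")
    pd.DataFrame(
        [{"sample_id": s.sample_id, "group": s.group, "scc": s.scc}
         for s in samples]
    ).to_csv(paths["samples"], sep="\t", index=False)
    qtl.to_csv(paths["qtl"], sep="\t", index=False)
    gwas.to_csv(paths["gwas"], sep="\t", index=False)
    from .formats_io import write_gmt
    write_gmt(gmt, paths["gmt"])
    truth.to_json(paths["truth"])
    return {"paths": {k: str(v) for k, v in paths.items()}, "truth": truth,
            "config": cfg}
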