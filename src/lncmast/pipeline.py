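"""End-to-end orchestration: identify -> DE -> modules -> targets ->
integration -> ORA, from one configuration object.

Each stage consumes only the outputs of earlier stages (the run is a DAG);
a failure stops the run with a stage-tagged error.  ``run_demo`` generates
a full synthetic input set, runs the pipeline on it and scores every stage
against the planted ground truth.
"""

from __future__ import annotations

import dataclasses
import logging
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import (coexpression, diff_expr, enrichment, formats_io, integration,
               lncrna_identify, synthetic_data, target_prediction)
from .diff_expr import COMPARISONS

log = logging.getLogger("lncmast")


class PipelineError(RuntimeError):
    """Raised with a stage tag when a stage fails."""


@dataclass
class RunConfig:
    """All stage thresholds plus input paths and stage toggles."""

    # inputs
    assembly_gtf: str = ""
    reference_gtf: str = ""
    fasta: str = ""
    counts: str = ""
    samples: str = ""
    qtl: str = ""
    gwas: str = ""
    gmt: str = ""
    outdir: str = "lncmast_out"
    seed: int = 0
    # identification
    min_exons: int = 2
    min_length: int = 200
    min_count: int = 1
    # differential expression
    prefilter_min_count: int = 10
    prefilter_min_samples: int = 2
    lfc_thr: float = 1.0
    p_thr: float = 0.05
    # co-expression
    r2_target: float = 0.9
    min_module_size: int = 30
    # targets
    window: int = 100_000
    r_thr: float = 0.95
    ndg_thr: float = -0.08
    # integration
    ext: int = 50_000
    n_perm: int = 200
    gwas_sig_thr: float = 5e-8
    # enrichment
    ora_padj_thr: float = 0.05
    # toggles
    stages: tuple[str, ...] = ("identify", "de", "modules", "targets",
                               "integrate", "ora")

    def params(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


@dataclass
class PipelineResult:
    catalog: list = field(default_factory=list)
    scores: dict = field(default_factory=dict)
    de_results: dict[str, pd.DataFrame] = field(default_factory=dict)
    shared_mrna: pd.DataFrame | None = None
    shared_lnc: pd.DataFrame | None = None
    norm_expr: pd.DataFrame | None = None
    soft_threshold: object = None
    modules: list = field(default_factory=list)
    module_trait: pd.DataFrame | None = None
    target_pairs: list = field(default_factory=list)
    scc_regressions: pd.DataFrame | None = None
    network: pd.DataFrame | None = None
    qtl_overlap: pd.DataFrame | None = None
    gwas_results: list = field(default_factory=list)
    ora_results: dict[str, list] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _require(config: RunConfig, attrs: list[str], stage: str) -> None:
    missing = [a for a in attrs if not getattr(config, a)]
    if missing:
        raise PipelineError(
            f"stage {stage}: missing input path(s) {missing} in configuration"
        )


def _feature_row(t, counts_index: set) -> str | None:
    """Count-matrix row for a transcript: its own id, else its gene id."""
    if t.transcript_id in counts_index:
        return t.transcript_id
    if t.gene_id in counts_index:
        return t.gene_id
    return None


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the enabled stages in order and write stage TSVs plus a
    manifest to ``config.outdir``."""
    # --- validate inputs up front (before any compute) --------------------
    _require(config, ["assembly_gtf", "reference_gtf", "fasta", "counts",
                      "samples"], "inputs")
    if "integrate" in config.stages:
        _require(config, ["qtl", "gwas"], "integrate")
    if "ora" in config.stages:
        _require(config, ["gmt"], "ora")

    res = PipelineResult()
    tables: dict[str, pd.DataFrame] = {}

    assembly = formats_io.read_gtf(config.assembly_gtf, source="assembly")
    reference = formats_io.read_gtf(config.reference_gtf, source="reference")
    sequences = formats_io.read_fasta(config.fasta)
    counts = formats_io.read_table(config.counts, "counts")
    samples = formats_io.read_table(config.samples, "samples")
    groups = pd.Series({s.sample_id: s.group for s in samples})
    scc = pd.Series({s.sample_id: s.scc for s in samples})
    counts_index = set(counts.index)
    for t in assembly.transcripts:
        row = _feature_row(t, counts_index)
        if row is not None:
            t.counts = counts.loc[row].values

    # map coding gene -> representative transcript sequence (for binding)
    gene_seq: dict[str, str] = {}
    gene_spans: dict[str, tuple[str, int, int]] = {}
    for t in assembly.transcripts:
        gene = reference.genes.get(t.gene_id)
        if gene is not None and gene.biotype == "protein_coding":
            gene_spans[t.gene_id] = (gene.chrom, gene.start, gene.end)
            if t.transcript_id in sequences:
                gene_seq.setdefault(t.gene_id, sequences[t.transcript_id])

    # --- identify ----------------------------------------------------------
    lnc_ids: set[str] = set()
    if "identify" in config.stages:
        try:
            tables_hex = _train_hexamer_tables(assembly, reference, sequences)
            res.catalog, res.scores = lncrna_identify.identify_lncrnas(
                assembly, reference, sequences,
                hexamer_tables=tables_hex,
                min_exons=config.min_exons, min_length=config.min_length,
                min_count=config.min_count,
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage identify: {exc}") from exc
        lnc_ids = {r.transcript_id for r in res.catalog}
        tables["lncrna_catalog"] = lncrna_identify.catalog_table(res.catalog)
        tables["coding_potential"] = pd.DataFrame(
            [{"transcript_id": s.transcript_id, "orf_length": s.orf_length,
              "fickett": s.fickett, "hexamer": s.hexamer,
              "composite": s.composite, "call": s.call}
             for s in res.scores.values()]
        ).sort_values("transcript_id", ignore_index=True)
        for name, tbl in lncrna_identify.feature_report(res.catalog).items():
            tables[f"report_{name}"] = tbl

    # count-matrix feature id for each catalog lncRNA
    tx_by_id = assembly.by_id()
    lnc_feature = {
        tid: _feature_row(tx_by_id[tid], counts_index) or tid
        for tid in lnc_ids
    }
    lnc_features = set(lnc_feature.values())

    # --- differential expression ------------------------------------------
    de_status: dict[str, str] = {}
    if "de" in config.stages:
        try:
            filtered = diff_expr.prefilter_counts(
                counts, config.prefilter_min_count, config.prefilter_min_samples)
            factors = diff_expr.size_factors(filtered)
            res.norm_expr = diff_expr.normalized_log(filtered, factors)
            for comp in COMPARISONS:
                raw = diff_expr.nb_wald_test(filtered, groups, comp)
                res.de_results[comp] = diff_expr.call_de(
                    raw, config.lfc_thr, config.p_thr)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage de: {exc}") from exc
        is_lnc = res.de_results["SFvsSC"]["feature_id"].isin(lnc_features)
        for comp, de in res.de_results.items():
            tables[f"de_{comp}"] = de
            for r in de.itertuples(index=False):
                if r.status != "ns":
                    de_status[r.feature_id] = r.status
        mrna = {c: de[~de["feature_id"].isin(lnc_features)]
                for c, de in res.de_results.items()}
        lncde = {c: de[de["feature_id"].isin(lnc_features)]
                 for c, de in res.de_results.items()}
        res.shared_mrna = diff_expr.shared_de(mrna["SFvsSC"], mrna["HFvsHC"])
        res.shared_lnc = diff_expr.shared_de(lncde["SFvsSC"], lncde["HFvsHC"])
        tables["shared_de_mrna"] = res.shared_mrna
        tables["shared_de_lncrna"] = res.shared_lnc

    # --- co-expression modules --------------------------------------------
    if "modules" in config.stages:
        if res.norm_expr is None:
            raise PipelineError("stage modules: requires the de stage")
        coding_expr = res.norm_expr.loc[
            [f for f in res.norm_expr.index
             if f in gene_spans and f not in lnc_features]
        ]
        try:
            res.soft_threshold = coexpression.pick_soft_threshold(
                coding_expr, r2_target=config.r2_target)
            res.modules = coexpression.detect_modules(
                coding_expr, res.soft_threshold.beta,
                min_module_size=config.min_module_size)
            traits = pd.get_dummies(groups).astype(float)
            traits["SCC"] = scc
            res.module_trait = coexpression.module_trait(
                res.modules, coding_expr, traits)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage modules: {exc}") from exc
        tables["module_assignment"] = pd.DataFrame(
            [{"gene": g, "module": m.module_id}
             for m in res.modules for g in sorted(m.members)]
        )
        tables["module_trait"] = res.module_trait
        tables["soft_threshold"] = res.soft_threshold.candidates

    # --- target prediction --------------------------------------------------
    de_lnc_by_comp: dict[str, list[str]] = {}
    if "targets" in config.stages:
        if not res.de_results:
            raise PipelineError("stage targets: requires the de stage")
        try:
            pairs: list[target_prediction.TargetPair] = []
            feature_to_tid = {v: k for k, v in lnc_feature.items()}
            for comp, de in res.de_results.items():
                de_ids = diff_expr.de_set(de)
                de_lnc = sorted(de_ids & lnc_features)
                de_mrna = sorted(de_ids - lnc_features)
                de_lnc_by_comp[comp] = de_lnc
                spans = {}
                for f in de_lnc:
                    t = tx_by_id.get(feature_to_tid.get(f, f))
                    if t is not None:
                        spans[f] = (t.chrom, t.start, t.end)
                pairs += target_prediction.cis_targets(
                    spans, gene_spans, window=config.window)
                comp_samples = [s for s in groups.index
                                if groups[s] in COMPARISONS[comp]]
                pairs += target_prediction.trans_targets(
                    res.norm_expr, de_lnc, de_mrna, comp_samples,
                    r_thr=config.r_thr, p_thr=config.p_thr)
            res.target_pairs = target_prediction.merge_target_modes(pairs)
            pair_seqs = dict(gene_seq)
            for f, tid in feature_to_tid.items():
                if tid in sequences:
                    pair_seqs[f] = sequences[tid]
            target_prediction.screen_pairs(
                res.target_pairs, pair_seqs, ndg_thr=config.ndg_thr)
            # SCC association of target genes
            reg_rows = []
            for gid in sorted({p.gene_id for p in res.target_pairs}):
                if gid in res.norm_expr.index and scc.std() > 0:
                    slope, r, p = target_prediction.scc_regression(
                        res.norm_expr.loc[gid, scc.index], scc)
                    reg_rows.append({"gene_id": gid, "slope": slope,
                                     "r": r, "pvalue": p})
            res.scc_regressions = pd.DataFrame(
                reg_rows, columns=["gene_id", "slope", "r", "pvalue"])
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage targets: {exc}") from exc
        tables["target_pairs"] = target_prediction.target_table(res.target_pairs)
        tables["scc_regression"] = res.scc_regressions

    # --- QTL / GWAS integration ---------------------------------------------
    if "integrate" in config.stages:
        try:
            qtl = formats_io.read_table(config.qtl, "qtl")
            gwas = formats_io.read_table(config.gwas, "gwas")
            feature_to_tid = {v: k for k, v in lnc_feature.items()}
            de_lnc_all = sorted({f for ids in de_lnc_by_comp.values()
                                 for f in ids})
            spans = {}
            for f in de_lnc_all:
                t = tx_by_id.get(feature_to_tid.get(f, f))
                if t is not None:
                    spans[f] = (t.chrom, t.start, t.end)
            res.qtl_overlap = integration.qtl_overlap(
                spans, qtl, window=config.window)
            # four gene sets: DE genes and DE-lncRNA target genes per comparison
            gene_sets = {}
            for comp, de in res.de_results.items():
                tag = "S" if comp == "SFvsSC" else "H"
                degs = set(diff_expr.de_set(de)) - lnc_features
                gene_sets[f"DEG-{tag}"] = degs & set(gene_spans)
                lnc_comp = set(de_lnc_by_comp.get(comp, []))
                dtgs = {p.gene_id for p in res.target_pairs
                        if p.lnc_id in lnc_comp}
                gene_sets[f"DTG-{tag}"] = dtgs & set(gene_spans)
            for trait, snps in gwas.groupby("trait"):
                for set_name, members in gene_sets.items():
                    if not members:
                        continue
                    res.gwas_results.append(integration.gwas_sum_enrichment(
                        members, gene_spans, snps, trait=str(trait),
                        gene_set_name=set_name, ext=config.ext,
                        n_perm=config.n_perm, seed=config.seed,
                    ))
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage integrate: {exc}") from exc
        tables["qtl_overlap"] = res.qtl_overlap
        tables["gwas_enrichment"] = integration.enrichment_table(
            res.gwas_results)

    # --- over-representation analysis ----------------------------------------
    if "ora" in config.stages:
        try:
            gmt = formats_io.read_table(config.gmt, "gmt")
            universe = set(
                diff_expr.prefilter_counts(
                    counts, config.prefilter_min_count,
                    config.prefilter_min_samples).index
            ) & set(gene_spans)
            ora_tables = []
            for comp, de in res.de_results.items():
                study = (set(diff_expr.de_set(de)) - lnc_features) & universe
                results = enrichment.ora(study, gmt, universe)
                res.ora_results[comp] = results
                tbl = enrichment.ora_table(results)
                tbl.insert(0, "comparison", comp)
                ora_tables.append(tbl)
            if ora_tables:
                tables["ora"] = pd.concat(ora_tables, ignore_index=True)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage ora: {exc}") from exc

    # --- regulatory network ---------------------------------------------------
    if "targets" in config.stages:
        pathway_hits = {}
        for comp, results in res.ora_results.items():
            for r in enrichment.significant_terms(results, config.ora_padj_thr):
                desc, members = formats_io.read_table(config.gmt, "gmt")[r.term_id]
                pathway_hits[r.term_id] = set(members)
        res.network = target_prediction.build_network(
            res.target_pairs, de_status, pathway_hits)
        tables["network_edges"] = res.network

    input_paths = {k: getattr(config, k)
                   for k in ("assembly_gtf", "reference_gtf", "fasta",
                             "counts", "samples", "qtl", "gwas", "gmt")
                   if getattr(config, k)}
    res.manifest = formats_io.write_results(
        tables, config.outdir, params=config.params(), input_paths=input_paths)
    return res


def _train_hexamer_tables(assembly, reference, sequences,
                          min_training_nt: int = 100_000):
    """Train coding/noncoding hexamer tables on the reference-matched
    transcripts ('=' to protein_coding vs '=' to lncRNA).

    The coding table is trained in frame on the longest-ORF region of each
    coding transcript (UTRs would dilute the codon signal); the noncoding
    table on full lncRNA sequences.  A 4096-bin frequency table needs tens
    of kilobases of sequence to beat its pseudocounts, so when either class
    provides fewer than ``min_training_nt`` nt the analytic default tables
    are used instead.
    """
    coding_seqs, noncoding_seqs = [], []
    for t in assembly.transcripts:
        if t.class_code != "=" or t.transcript_id not in sequences:
            continue
        bt = None
        if t.cmp_ref is not None:
            bt = reference.transcript_biotype.get(t.cmp_ref)
        if bt is None:
            gene = reference.genes.get(t.gene_id)
            bt = gene.biotype if gene else None
        if bt == "protein_coding":
            seq = sequences[t.transcript_id]
            start, length = lncrna_identify.longest_orf(seq)
            coding_seqs.append(seq[start:start + length] if length else seq)
        elif bt == "lncRNA":
            noncoding_seqs.append(sequences[t.transcript_id])
    if (sum(map(len, coding_seqs)) < min_training_nt
            or sum(map(len, noncoding_seqs)) < min_training_nt):
        log.info("too little reference-matched sequence to train hexamer "
                 "tables; using analytic defaults")
        return lncrna_identify.default_hexamer_tables()
    return {
        "coding": lncrna_identify.train_hexamer_table(coding_seqs, step=3),
        "noncoding": lncrna_identify.train_hexamer_table(noncoding_seqs),
    }


# ---------------------------------------------------------------------------
# Demo on synthetic data
# ---------------------------------------------------------------------------

def score_against_truth(res: PipelineResult,
                        truth: synthetic_data.GroundTruth) -> dict:
    """Recovery metrics of a pipeline run against the planted ground truth."""
    from sklearn.metrics import adjusted_rand_score

    metrics: dict = {}
    # identification
    identified = {r.transcript_id for r in res.catalog}
    true_set = set(truth.true_lncRNAs)
    tp = len(identified & true_set)
    metrics["identify_sensitivity"] = tp / len(true_set) if true_set else np.nan
    metrics["identify_precision"] = tp / len(identified) if identified else np.nan
    # differential expression (scored on testable features; genes carrying
    # other planted structure — modules tied to group membership, SCC-linked
    # genes — are genuinely differential and are excluded from FDR scoring)
    if res.de_results:
        structured = set(truth.planted_scc_genes)
        for mod in truth.planted_modules.values():
            structured |= set(mod["genes"])
        called, truthful = set(), set()
        tested: set = set()
        for comp, de in res.de_results.items():
            tested |= {(comp, f) for f in de["feature_id"]}
            called |= {(comp, f) for f in diff_expr.de_set(de)
                       if f not in structured}
            truthful |= {(comp, f) for f in truth.planted_DE.get(comp, {})}
        truthful &= tested
        tp = len(called & truthful)
        metrics["de_sensitivity"] = tp / len(truthful) if truthful else np.nan
        metrics["de_fdr"] = (len(called - truthful) / len(called)
                             if called else 0.0)
    # modules
    if res.modules:
        assign = {g: m.module_id for m in res.modules for g in m.members}
        genes, labels_true, labels_pred = [], [], []
        for mid, mod in truth.planted_modules.items():
            for g in mod["genes"]:
                if g in assign:
                    genes.append(g)
                    labels_true.append(mid)
                    labels_pred.append(assign[g])
        metrics["module_ari"] = (
            float(adjusted_rand_score(labels_true, labels_pred))
            if genes else np.nan
        )
    # targets
    if res.target_pairs:
        found = {(p.lnc_id, p.gene_id) for p in res.target_pairs}
        planted_trans = {(l, g) for l, g, m in truth.planted_targets
                         if m == "trans"}
        feature_pairs = {(l, g) for l, g in planted_trans}
        metrics["trans_target_recovery"] = (
            len(found & feature_pairs) / len(feature_pairs)
            if feature_pairs else np.nan
        )
    # QTL
    if res.qtl_overlap is not None:
        rows = {(r.lnc_id, r.qtl_id) for r in res.qtl_overlap.itertuples()}
        planted = set(truth.planted_qtl_hits)
        metrics["qtl_hits_recovered"] = (
            len(rows & planted) / len(planted) if planted else np.nan)
        # decoys are guaranteed distant only from *planted* DE lncRNAs; a
        # decoy near a false-positive DE call is expected behavior
        planted_de_lnc = {f for e in truth.planted_DE.values() for f in e
                          if f in truth.true_lncRNAs}
        metrics["qtl_decoys_excluded"] = float(not any(
            q in truth.decoy_qtl_ids and l in planted_de_lnc
            for l, q in rows))
    # GWAS
    if res.gwas_results:
        hits = [r for r in res.gwas_results
                if r.trait == truth.planted_gwas_trait
                and r.gene_set_name.startswith("DEG")]
        if hits:
            metrics["gwas_planted_min_emp_p"] = min(r.emp_p for r in hits)
    return metrics


def run_demo(seed: int, outdir: str | Path | None = None,
             keep: bool = False, n_perm: int = 200) -> dict:
    """Generate synthetic inputs, run the full pipeline, score against the
    ground truth and return the recovery metrics.  Uses a temporary
    directory unless ``outdir`` is given; cleans it up on success unless
    ``keep`` is True."""
    tmpdir = Path(outdir) if outdir else Path(tempfile.mkdtemp(prefix="lncmast_"))
    try:
        gen = synthetic_data.generate_all(seed, tmpdir / "inputs")
        paths = gen["paths"]
        config = RunConfig(
            assembly_gtf=paths["assembly_gtf"],
            reference_gtf=paths["reference_gtf"],
            fasta=paths["fasta"], counts=paths["counts"],
            samples=paths["samples"], qtl=paths["qtl"], gwas=paths["gwas"],
            gmt=paths["gmt"], outdir=str(tmpdir / "results"), seed=seed,
            n_perm=n_perm,
        )
        res = run_pipeline(config)
        metrics = score_against_truth(res, gen["truth"])
        metrics["n_lncRNAs_identified"] = len(res.catalog)
        metrics["n_de_lnc_SFvsSC"] = len(
            set(diff_expr.de_set(res.de_results["SFvsSC"]))
            & set(gen["truth"].lnc_transcripts))
        return metrics
    finally:
        if outdir is None and not keep:
            shutil.rmtree(tmpdir, ignore_errors=True)
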