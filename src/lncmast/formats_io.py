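"""Readers and writers for every external format the pipeline touches.

Supported formats
-----------------
* GTF in two dialects: an Ensembl-style *reference* annotation carrying
  ``gene_biotype`` / ``transcript_biotype`` attributes, and a
  StringTie/gffcompare-style *assembly* annotation carrying ``class_code``
  (and optionally ``cmp_ref``, the matched reference transcript).
* Transcript sequences as FASTA (via Biopython).
* Tabular inputs as TSV: a features x samples count matrix, a QTL interval
  table, a GWAS SNP summary table, an external coding-potential score table.
* Gene sets as GMT.
* Stage outputs as TSVs plus a JSON run manifest.

Conventions
-----------
All genomic coordinates are 1-based inclusive internally; any conversion
happens only at the I/O boundary.  Chromosome names are normalized by
stripping a leading ``chr`` prefix.  The count matrix is features-in-rows;
no auto-transposing is attempted.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("lncmast")

GROUPS = ("SF", "SC", "HF", "HC")
"""Experimental groups: subclinical-mastitis folic-acid fed / control,
healthy fed / control."""


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


class SchemaError(ValueError):
    """A table violates its declared schema."""


class ConsistencyError(ValueError):
    """Records contradict each other (e.g. one transcript on two strands)."""


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr``/``Chr`` prefix so inputs can be mixed."""
    return chrom[3:] if chrom[:3].lower() == "chr" else chrom


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneRecord:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "unknown"


@dataclass
class TranscriptModel:
    """One assembled or reference transcript with its exon structure.

    ``exons`` are (start, end) pairs, 1-based inclusive, sorted and
    non-overlapping.  ``counts`` is the per-sample read-count vector once
    attached (same sample order as the count matrix columns).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    class_code: str = "unknown"
    cmp_ref: str | None = None
    counts: np.ndarray | None = None

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        ]


@dataclass
class AnnotationBundle:
    """Transcripts plus a gene table; the carrier between pipeline stages."""

    transcripts: list[TranscriptModel] = field(default_factory=list)
    genes: dict[str, GeneRecord] = field(default_factory=dict)
    transcript_biotype: dict[str, str] = field(default_factory=dict)

    def by_id(self) -> dict[str, TranscriptModel]:
        return {t.transcript_id: t for t in self.transcripts}

    def novel_gene_ids(self) -> set[str]:
        return {t.gene_id for t in self.transcripts if t.gene_id not in self.genes}


@dataclass
class SampleMeta:
    """One sequenced animal: group label and somatic cell count phenotype.

    ``scc`` is in units of x1000 cells/mL milk; the subclinical-mastitis
    groups were classified at SCC > 500 x1000 cells/mL.
    """

    sample_id: str
    group: str
    scc: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise SchemaError(
                f"sample {self.sample_id}: group {self.group!r} not in {GROUPS}"
            )
        if self.scc < 0:
            raise SchemaError(f"sample {self.sample_id}: negative SCC {self.scc}")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"')


def _parse_attrs(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(path: str | Path, source: str = "assembly") -> AnnotationBundle:
    """Read a GTF file into an :class:`AnnotationBundle`.

    Parameters
    ----------
    path
        9-column GTF file.
    source
        ``"reference"`` (Ensembl dialect, carries biotypes) or
        ``"assembly"`` (StringTie/gffcompare dialect, carries class codes).
        Assembly records with no ``class_code`` attribute are stored with
        class code ``"unknown"``.
    """
    if source not in ("reference", "assembly"):
        raise ValueError(f"source must be 'reference' or 'assembly', got {source!r}")
    path = Path(path)
    exons: dict[str, list[tuple[int, int]]] = {}
    tx_info: dict[str, dict] = {}
    genes: dict[str, GeneRecord] = {}
    tx_biotype: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path.name} line {lineno}: expected 9 tab-separated "
                    f"columns, got {len(fields)}"
                )
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(
                    f"{path.name} line {lineno}: non-integer coordinate"
                ) from exc
            if start > end:
                raise ParseError(f"{path.name} line {lineno}: start > end")
            chrom = normalize_chrom(chrom)
            attrs = _parse_attrs(attrs_s)
            if feature == "gene":
                gid = attrs.get("gene_id")
                if gid is None:
                    raise ParseError(f"{path.name} line {lineno}: gene without gene_id")
                genes[gid] = GeneRecord(
                    gid, chrom, start, end, strand,
                    attrs.get("gene_biotype", "unknown"),
                )
                continue
            if feature not in ("transcript", "exon"):
                continue
            tid = attrs.get("transcript_id")
            if tid is None:
                raise ParseError(
                    f"{path.name} line {lineno}: {feature} without transcript_id"
                )
            info = tx_info.setdefault(
                tid,
                {
                    "gene_id": attrs.get("gene_id", tid),
                    "chrom": chrom,
                    "strand": strand,
                    "class_code": "unknown",
                    "cmp_ref": None,
                },
            )
            if info["chrom"] != chrom or info["strand"] != strand:
                raise ConsistencyError(
                    f"{path.name} line {lineno}: transcript {tid} seen on "
                    f"{info['chrom']}{info['strand']} and {chrom}{strand}"
                )
            if "class_code" in attrs:
                info["class_code"] = attrs["class_code"]
            if "cmp_ref" in attrs:
                info["cmp_ref"] = attrs["cmp_ref"]
            if "transcript_biotype" in attrs:
                tx_biotype[tid] = attrs["transcript_biotype"]
            if "gene_biotype" in attrs and info["gene_id"] not in genes:
                genes[info["gene_id"]] = GeneRecord(
                    info["gene_id"], chrom, start, end, strand,
                    attrs["gene_biotype"],
                )
            if feature == "exon":
                exons.setdefault(tid, []).append((start, end))

    transcripts = []
    for tid, info in tx_info.items():
        ex = sorted(exons.get(tid, []))
        if not ex:
            log.warning("transcript %s has no exon records; skipped", tid)
            continue
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 <= e1:
                raise ConsistencyError(
                    f"transcript {tid}: overlapping exons {(s1, e1)} / {(s2, e2)}"
                )
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=info["gene_id"],
                chrom=info["chrom"],
                strand=info["strand"],
                exons=ex,
                class_code=info["class_code"],
                cmp_ref=info["cmp_ref"],
            )
        )
    # extend gene bounds to cover all their transcripts
    for t in transcripts:
        g = genes.get(t.gene_id)
        if g is not None:
            g.start = min(g.start, t.start)
            g.end = max(g.end, t.end)
    return AnnotationBundle(transcripts=transcripts, genes=genes,
                            transcript_biotype=tx_biotype)


def write_gtf(bundle: AnnotationBundle, path: str | Path,
              dialect: str = "assembly") -> None:
    """Write an :class:`AnnotationBundle` as GTF (inverse of :func:`read_gtf`)."""
    path = Path(path)
    lines = []
    if dialect == "reference":
        for gid in sorted(bundle.genes):
            g = bundle.genes[gid]
            lines.append(
                f"{g.chrom}\tlncmast\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f'gene_id "{gid}"; gene_biotype "{g.biotype}";'
            )
    for t in sorted(bundle.transcripts, key=lambda t: t.transcript_id):
        attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
        if dialect == "assembly":
            if t.class_code != "unknown":
                attrs += f' class_code "{t.class_code}";'
            if t.cmp_ref:
                attrs += f' cmp_ref "{t.cmp_ref}";'
        else:
            bt = bundle.transcript_biotype.get(t.transcript_id)
            if bt:
                attrs += f' transcript_biotype "{bt}";'
        lines.append(
            f"{t.chrom}\tlncmast\ttranscript\t{t.start}\t{t.end}\t.\t{t.strand}\t.\t{attrs}"
        )
        for s, e in t.exons:
            lines.append(
                f"{t.chrom}\tlncmast\texon\t{s}\t{e}\t.\t{t.strand}\t.\t{attrs}"
            )
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read transcript sequences; returns id -> uppercase sequence."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=tid, description="")
        for tid, seq in sorted(sequences.items())
    ]
    seqio_write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

_TABLE_SCHEMAS = ("counts", "qtl", "gwas", "gmt", "scores", "samples")


def read_table(path: str | Path, schema: str):
    """Read and validate one of the pipeline's tabular inputs.

    ``schema`` is one of ``counts`` (features x samples integer matrix),
    ``qtl`` (chrom, start, end, trait, qtl_id), ``gwas`` (chrom, pos, trait,
    pvalue), ``gmt`` (standard GMT; returns term -> (description, members)),
    ``scores`` (transcript_id plus per-predictor numeric columns) or
    ``samples`` (sample_id, group, scc; returns a list of SampleMeta).
    """
    if schema not in _TABLE_SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    path = Path(path)
    if schema == "gmt":
        return _read_gmt(path)

    df = pd.read_csv(path, sep="\t")
    if schema == "counts":
        df = df.set_index(df.columns[0])
        df.index.name = "feature_id"
        for col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                bad = df.index[vals.isna()][0]
                raise SchemaError(f"counts: non-numeric value at ({bad}, {col})")
            if (vals < 0).any():
                bad = df.index[vals < 0][0]
                raise SchemaError(f"counts: negative count at ({bad}, {col})")
            if not np.allclose(vals, np.round(vals)):
                bad = df.index[vals != np.round(vals)][0]
                raise SchemaError(f"counts: non-integer count at ({bad}, {col})")
        return df.round().astype(np.int64)

    if schema == "qtl":
        _require_columns(df, ["chrom", "start", "end", "trait", "qtl_id"], "qtl")
        df["chrom"] = df["chrom"].astype(str).map(normalize_chrom)
        for col in ("start", "end"):
            df[col] = _positive_int(df, col, "qtl")
        if (df["start"] > df["end"]).any():
            bad = df.index[df["start"] > df["end"]][0]
            raise SchemaError(f"qtl row {bad}: start > end")
        df["qtl_id"] = df["qtl_id"].astype(str)
        return df

    if schema == "gwas":
        _require_columns(df, ["chrom", "pos", "trait", "pvalue"], "gwas")
        df["chrom"] = df["chrom"].astype(str).map(normalize_chrom)
        df["pos"] = _positive_int(df, "pos", "gwas")
        pv = pd.to_numeric(df["pvalue"], errors="coerce")
        bad = pv.isna() | (pv <= 0) | (pv > 1)
        if bad.any():
            raise SchemaError(
                f"gwas row {df.index[bad][0]}: p-value outside (0, 1]"
            )
        df["pvalue"] = pv
        return df

    if schema == "samples":
        _require_columns(df, ["sample_id", "group", "scc"], "samples")
        return [
            SampleMeta(str(r.sample_id), str(r.group), float(r.scc))
            for r in df.itertuples(index=False)
        ]

    # scores
    if "transcript_id" not in df.columns:
        raise SchemaError("scores: missing mandatory column 'transcript_id'")
    for col in df.columns:
        if col == "transcript_id":
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.index[vals.isna()][0]
            raise SchemaError(f"scores: non-numeric value at ({bad}, {col})")
        df[col] = vals
    return df.set_index("transcript_id")


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing mandatory column(s) {missing}")


def _positive_int(df: pd.DataFrame, col: str, name: str) -> pd.Series:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() | (vals < 1) | (vals != np.round(vals))
    if bad.any():
        raise SchemaError(f"{name} row {df.index[bad][0]}: bad value in {col!r}")
    return vals.astype(np.int64)


def _read_gmt(path: Path) -> dict[str, tuple[str, frozenset[str]]]:
    gmt: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path.name} line {lineno}: fewer than 2 columns")
            term, desc, *members = parts
            members = [m for m in members if m]
            if not members:
                log.warning("GMT term %s has no members", term)
            gmt[term] = (desc, frozenset(members))
    return gmt


def write_gmt(gmt: dict[str, tuple[str, frozenset[str]]], path: str | Path) -> None:
    lines = [
        "\t".join([term, desc, *sorted(members)])
        for term, (desc, members) in sorted(gmt.items())
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(tables: dict[str, pd.DataFrame], outdir: str | Path,
                  params: dict | None = None,
                  input_paths: dict[str, str | Path] | None = None) -> dict:
    """Write one TSV per stage table plus a JSON manifest.

    The manifest records the run parameters, the checksum of every written
    table and of every input file, so that re-runs with the same seed and
    configuration can be verified byte-for-byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": params or {}, "outputs": {}, "inputs": {}}
    for name, table in tables.items():
        dest = outdir / f"{name}.tsv"
        table.to_csv(dest, sep="\t", index=False, float_format="%.6g",
                     lineterminator="\n")
        manifest["outputs"][name] = {"path": dest.name, "sha256": _sha256(dest),
                                     "rows": int(len(table))}
    for name, p in (input_paths or {}).items():
        p = Path(p)
        if p.exists():
            manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
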