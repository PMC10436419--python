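"""Shared fixtures: one session-scoped synthetic world plus the printed
worked-example tables."""

from pathlib import Path

import pandas as pd
import pytest

from lncmast import synthetic_data as sd

DATA = Path(__file__).parent / "data"
WORLD_SEED = 42


@pytest.fixture(scope="session")
def synth_world():
    """A complete generated world at a fixed seed: annotation, counts,
    sequences, QTL/GWAS tables and the ground truth."""
    cfg = sd.SyntheticConfig()
    assembly, reference, truth = sd.generate_annotation(WORLD_SEED, cfg)
    samples = sd.make_samples(WORLD_SEED, cfg)
    counts = sd.generate_counts(assembly, truth, samples, WORLD_SEED, cfg)
    sequences = sd.generate_sequences(assembly, truth, WORLD_SEED)
    qtl, gwas = sd.generate_qtl_gwas(assembly, truth, WORLD_SEED, cfg)
    return {
        "config": cfg, "assembly": assembly, "reference": reference,
        "truth": truth, "samples": samples, "counts": counts,
        "sequences": sequences, "qtl": qtl, "gwas": gwas,
    }


@pytest.fixture(scope="session")
def printed_de_tables():
    """The shared-DE worked examples printed for both comparisons."""
    return {
        "mrna": pd.read_csv(DATA / "shared_de_mrna_printed.tsv", sep="\t"),
        "lncrna": pd.read_csv(DATA / "shared_de_lncrna_printed.tsv", sep="\t"),
    }


@pytest.fixture(scope="session")
def printed_qtl_table():
    """The printed lncRNA/QTL coordinate pairs (12 rows)."""
    return pd.read_csv(DATA / "qtl_overlap_printed.tsv", sep="\t")
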