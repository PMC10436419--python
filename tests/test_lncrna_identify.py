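"""Identification cascade: ORF finder, Fickett statistic, hexamer scores,
consensus logic, filters, classification, reporting."""

import numpy as np
import pandas as pd
import pytest

from lncmast import lncrna_identify as li
from lncmast.formats_io import AnnotationBundle, GeneRecord, TranscriptModel


def _tx(tid, class_code="u", exons=((1, 500), (601, 1100)), counts=(5, 0),
        gene="g", chrom="1", strand="+", cmp_ref=None):
    return TranscriptModel(tid, gene, chrom, strand, list(exons),
                           class_code=class_code, cmp_ref=cmp_ref,
                           counts=np.array(counts))


class TestLongestOrf:
    @pytest.mark.parametrize("seq,expected", [
        ("ATGAAATAA", 9),                      # one codon + stop
        ("ATGAAA", 0),                         # no stop: not a complete ORF
        ("CCATGAAATAACC", 9),                  # off-frame offset
        ("ATGTAAATGAAAAAATAA", 12),            # longest of two wins
        ("", 0),
    ])
    def test_known_cases(self, seq, expected):
        assert li.longest_orf(seq)[1] == expected

    def test_tie_broken_toward_five_prime(self):
        # two 9-nt ORFs in different frames; the earlier start must win
        seq = "ATGAAATAAG" + "ATGCCCTGA"
        start, length = li.longest_orf(seq)
        assert (start, length) == (0, 9)

    def test_nested_start_does_not_shorten(self):
        # ATG ATG AAA TAA: ORF runs from the first ATG
        start, length = li.longest_orf("ATGATGAAATAA")
        assert (start, length) == (0, 12)


def _fickett_reference(seq):
    """Independent literal transcription of the published TESTCODE lookup
    procedure, kept deliberately separate from the implementation."""
    pos_prob = {
        "A": [.94, .68, .84, .93, .58, .68, .45, .34, .20, .22],
        "C": [.80, .70, .70, .81, .66, .48, .51, .33, .30, .23],
        "G": [.90, .88, .74, .64, .53, .48, .27, .16, .08, .08],
        "T": [.97, .97, .91, .68, .69, .44, .54, .20, .09, .09]}
    pos_w = {"A": .26, "C": .18, "G": .31, "T": .33}
    pos_cut = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]
    con_prob = {
        "A": [.28, .49, .44, .55, .62, .49, .67, .65, .81, .21],
        "C": [.82, .64, .51, .64, .59, .59, .43, .44, .39, .31],
        "G": [.40, .54, .47, .64, .64, .73, .41, .41, .33, .29],
        "T": [.28, .24, .39, .40, .55, .75, .56, .69, .51, .58]}
    con_w = {"A": .11, "C": .12, "G": .15, "T": .14}
    con_cut = [.33, .31, .29, .27, .25, .23, .21, .19, .17, 0.0]
    total = 0.0
    for base in "ACGT":
        c0 = sum(1 for i in range(0, len(seq), 3) if seq[i] == base)
        c1 = sum(1 for i in range(1, len(seq), 3) if seq[i] == base)
        c2 = sum(1 for i in range(2, len(seq), 3) if seq[i] == base)
        posv = max(c0, c1, c2) / (min(c0, c1, c2) + 1)
        conv = (c0 + c1 + c2) / len(seq)
        pp = next(p for cut, p in zip(pos_cut, pos_prob[base]) if posv >= cut)
        cp = next(p for cut, p in zip(con_cut, con_prob[base]) if conv >= cut)
        total += pp * pos_w[base] + cp * con_w[base]
    return total


class TestFickett:
    def test_matches_independent_transcription_on_fixed_sequences(self):
        """Three fixed 300-nt sequences spanning AT-rich, GC-rich and
        periodic composition; the two transcriptions must agree exactly."""
        rng = np.random.default_rng(17)
        seqs = [
            "".join(rng.choice(list("ACGT"), 300, p=[.35, .15, .15, .35])),
            "".join(rng.choice(list("ACGT"), 300, p=[.15, .35, .35, .15])),
            "ATGGCC" * 50,
        ]
        for seq in seqs:
            assert li.fickett_score(seq) == pytest.approx(
                _fickett_reference(seq), abs=1e-12)

    def test_coding_scores_above_noncoding_on_synthetic(self, synth_world):
        seqs, truth = synth_world["sequences"], synth_world["truth"]
        assembly = synth_world["assembly"]
        coding = [seqs[t.transcript_id] for t in assembly.transcripts
                  if t.gene_id.startswith("G") and t.class_code == "="][:40]
        noncoding = [seqs[t] for t in truth.true_lncRNAs][:40]
        med_c = np.median([li.fickett_score(s) for s in coding])
        med_n = np.median([li.fickett_score(s) for s in noncoding])
        assert med_c > med_n


class TestHexamer:
    def test_identical_tables_score_zero(self):
        tables = li.default_hexamer_tables()
        same = {"coding": tables["coding"], "noncoding": tables["coding"]}
        assert li.hexamer_score("ATGAAACCCGGGTTTTAA", same) == 0.0

    def test_no_orf_scores_zero(self):
        assert li.hexamer_score("CCCCCCCCCCCC", li.default_hexamer_tables()) == 0.0

    def test_trained_table_is_a_probability_distribution(self):
        table = li.train_hexamer_table(["ATGAAACCCGGG" * 10])
        assert pytest.approx(sum(table.values()), abs=1e-9) == 1.0
        assert len(table) == 4096


class TestScoreAndConsensus:
    def test_non_acgtn_characters_rejected(self):
        with pytest.raises(ValueError, match="non-ACGTN"):
            li.score_coding_potential({"t": "ACGTX"})

    def test_consensus_equals_set_intersection_oracle(self):
        """3 internal + 2 external predictors with random calls on 100
        transcripts: the consensus must equal the brute-force intersection
        of the per-predictor noncoding sets."""
        rng = np.random.default_rng(3)
        thr = li.CodingThresholds()
        scores = {}
        external = {"P1": {}, "P2": {}}
        noncoding_by_predictor = {k: set() for k in
                                  ("orf", "fickett", "composite", "P1", "P2")}
        for i in range(100):
            tid = f"t{i}"
            orf = int(rng.choice([0, 150, 450]))
            fick = float(rng.choice([0.5, 1.2]))
            hexa = float(rng.choice([-1.0, 1.0]))
            comp = float(rng.choice([0.2, 0.8]))
            scores[tid] = li.CodingPotentialScores(tid, orf, fick, hexa, comp)
            if orf < thr.orf and (orf == 0 or hexa < thr.hexamer):
                noncoding_by_predictor["orf"].add(tid)
            if fick < thr.fickett:
                noncoding_by_predictor["fickett"].add(tid)
            if comp < thr.composite:
                noncoding_by_predictor["composite"].add(tid)
            for p in ("P1", "P2"):
                call = str(rng.choice(["coding", "noncoding"]))
                external[p][tid] = call
                if call == "noncoding":
                    noncoding_by_predictor[p].add(tid)
        oracle = set.intersection(*noncoding_by_predictor.values())
        result = li.consensus_call(scores, thr, external)
        assert result == oracle

    def test_missing_external_entry_treated_as_coding(self, caplog):
        scores = {"t1": li.CodingPotentialScores("t1", 0, 0.5, 0.0, 0.1)}
        with caplog.at_level("WARNING", logger="lncmast"):
            out = li.consensus_call(scores, external={"PLEK": {}})
        assert out == set() and scores["t1"].call == "coding"


class TestFilters:
    def _reference(self):
        ref = AnnotationBundle()
        ref.genes["gk"] = GeneRecord("gk", "1", 1, 2000, "+", "lncRNA")
        ref.transcript_biotype["gk.t1"] = "lncRNA"
        return ref

    def test_basic_filter_boundaries(self):
        known = _tx("known1", "=", exons=((1, 500),), counts=(3,),
                    gene="gk", cmp_ref="gk.t1")
        one_exon_novel = _tx("n1", "u", exons=((1, 500),))
        short = _tx("n2", "u", exons=((1, 99), (200, 299)))       # length 199
        boundary = _tx("n3", "u", exons=((1, 100), (200, 299)),
                       counts=(1, 0))                              # length 200
        zero = _tx("n4", "u", counts=(0, 0))
        kept = li.basic_filter([known, one_exon_novel, short, boundary, zero],
                               known_ids={"known1"})
        assert {t.transcript_id for t in kept} == {"known1", "n3"}

    def test_class_code_routing(self):
        ref = self._reference()
        u = _tx("a", "u")
        j = _tx("b", "j")
        eq = _tx("c", "=", gene="gk", cmp_ref="gk.t1")
        novel, known, discarded = li.class_code_filter([u, j, eq], ref)
        assert [t.transcript_id for t in novel] == ["a"]
        assert [t.transcript_id for t in known] == ["c"]
        assert [t.transcript_id for t in discarded] == ["b"]

    def test_filters_are_monotone_and_order_independent(self):
        ref = self._reference()
        txs = [_tx(f"t{i}", c, counts=(i % 3,))
               for i, c in enumerate(["u", "i", "x", "j", "=", "u"])]
        a = li.basic_filter(txs)
        novel_a, known_a, _ = li.class_code_filter(a, ref)
        novel_b, known_b, _ = li.class_code_filter(txs, ref)
        b = li.basic_filter(novel_b + known_b)
        assert set(t.transcript_id for t in a) <= set(t.transcript_id for t in txs)
        assert ({t.transcript_id for t in novel_a} | {t.transcript_id for t in known_a}
                == {t.transcript_id for t in b})


class TestClassifyAndReport:
    def test_category_mapping(self):
        novel = [_tx("a", "u"), _tx("b", "i"), _tx("c", "x")]
        known = [_tx("d", "=")]
        records = li.classify(novel, known)
        cats = {r.transcript_id: r.category for r in records}
        assert cats == {"a": "lincRNA", "b": "ilncRNA", "c": "lncNAT",
                        "d": "known"}
        assert all((r.category == "known") == (not r.novel) for r in records)

    def test_full_cascade_recovers_planted_classes(self, synth_world):
        """Catalog categories on the synthetic world equal the planted
        class counts (violators excluded by the filters)."""
        catalog, _ = li.identify_lncrnas(
            synth_world["assembly"], synth_world["reference"],
            synth_world["sequences"])
        truth = synth_world["truth"]
        got = pd.Series([r.category for r in catalog]).value_counts().to_dict()
        want = pd.Series(list(truth.true_lncRNAs.values())).value_counts().to_dict()
        assert got == want

    def test_feature_report_conserves_totals(self, synth_world):
        catalog, _ = li.identify_lncrnas(
            synth_world["assembly"], synth_world["reference"],
            synth_world["sequences"])
        report = li.feature_report(catalog)
        n = len(catalog)
        assert report["exon_hist"]["count"].sum() == n
        assert report["length_bins"]["count"].sum() == n
        assert report["category_counts"]["count"].sum() == n
        # per-chromosome counts equal a direct groupby
        df = li.catalog_table(catalog)
        direct = df.groupby("chrom").size()
        got = report["chrom_counts"].set_index("chrom")["count"]
        assert got.sort_index().equals(direct.sort_index())

    def test_empty_catalog_gives_empty_report(self):
        report = li.feature_report([])
        assert all(len(t) == 0 for t in report.values())
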