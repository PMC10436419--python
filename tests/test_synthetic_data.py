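"""Synthetic-world generator: placement rules, sequence structure,
count structure, QTL/GWAS planting."""

import numpy as np
import pytest

from lncmast import formats_io as fio
from lncmast import synthetic_data as sd
from lncmast.lncrna_identify import longest_orf


class TestAnnotation:
    def test_fixed_seed_is_deterministic(self, tmp_path):
        a1, r1, _ = sd.generate_annotation(5)
        a2, r2, _ = sd.generate_annotation(5)
        fio.write_gtf(a1, tmp_path / "a1.gtf")
        fio.write_gtf(a2, tmp_path / "a2.gtf")
        assert (tmp_path / "a1.gtf").read_text() == (tmp_path / "a2.gtf").read_text()

    def test_zero_lnc_classes_gives_only_coding(self):
        cfg = sd.SyntheticConfig(n_lnc_per_class=(0, 0, 0, 0), n_decoys=0)
        assembly, _, truth = sd.generate_annotation(1, cfg)
        assert truth.true_lncRNAs == {}
        assert all(t.class_code == "=" for t in assembly.transcripts)

    def test_intronic_lnc_strictly_inside_host_intron(self, synth_world):
        """Every class-i transcript must fall inside an intron of some
        coding transcript on its chromosome (interval containment)."""
        assembly = synth_world["assembly"]
        coding = [t for t in assembly.transcripts if t.class_code == "="
                  and t.gene_id.startswith("G")]
        for t in assembly.transcripts:
            if t.class_code != "i":
                continue
            contained = any(
                s < t.start and t.end < e
                for host in coding if host.chrom == t.chrom
                for s, e in host.introns()
            )
            assert contained, t.transcript_id

    def test_intergenic_lnc_beyond_window_of_genes(self, synth_world):
        ref = synth_world["reference"]
        window = synth_world["config"].window
        for t in synth_world["assembly"].transcripts:
            if t.class_code != "u":
                continue
            for g in ref.genes.values():
                if g.chrom != t.chrom:
                    continue
                gap = max(0, max(t.start, g.start) - min(t.end, g.end))
                assert gap > window, (t.transcript_id, g.gene_id)

    def test_antisense_lnc_overlaps_exon_opposite_strand(self, synth_world):
        assembly = synth_world["assembly"]
        coding = [t for t in assembly.transcripts if t.class_code == "="
                  and t.gene_id.startswith("G")]
        for t in assembly.transcripts:
            if t.class_code != "x":
                continue
            hit = any(
                host.strand != t.strand
                and any(es <= t.end and t.start <= ee for es, ee in host.exons)
                for host in coding if host.chrom == t.chrom
            )
            assert hit, t.transcript_id

    def test_violator_fraction_planted(self, synth_world):
        truth = synth_world["truth"]
        n_nc = len(truth.lnc_transcripts)
        assert 0.10 * n_nc <= len(truth.violators) <= 0.20 * n_nc


class TestSequences:
    def test_coding_transcripts_carry_long_orf(self, synth_world):
        truth, seqs = synth_world["truth"], synth_world["sequences"]
        assembly = synth_world["assembly"]
        coding = [t for t in assembly.transcripts
                  if t.gene_id.startswith("G") and t.class_code == "="
                  and t.length >= 900]
        assert coding
        for t in coding[:50]:
            _, orf = longest_orf(seqs[t.transcript_id])
            assert orf >= 300

    def test_noncoding_orfs_short_in_at_least_90_percent(self, synth_world):
        truth, seqs = synth_world["truth"], synth_world["sequences"]
        lncs = [t for t in truth.true_lncRNAs]
        short = sum(longest_orf(seqs[t])[1] < 150 for t in lncs)
        assert short / len(lncs) >= 0.9

    def test_sequence_length_matches_annotation_and_gc_bounds(self, synth_world):
        by_id = synth_world["assembly"].by_id()
        for tid, seq in synth_world["sequences"].items():
            assert len(seq) == by_id[tid].length
            gc = (seq.count("G") + seq.count("C")) / len(seq)
            assert 0.3 <= gc <= 0.7

    def test_empty_annotation_gives_empty_fasta(self):
        empty = fio.AnnotationBundle()
        seqs = sd.generate_sequences(empty, sd.GroundTruth(), 1)
        assert seqs == {}


class TestCounts:
    def test_size_factor_truth_recoverable_in_near_poisson_world(self):
        """With equal means and alpha -> 0, median-of-ratios factors must
        match the planted library factors (the normalization oracle)."""
        from lncmast.diff_expr import size_factors
        # a clean world: no planted effects or modules, so every feature's
        # mean is shared across samples up to the library factor
        cfg = sd.SyntheticConfig(
            dispersion_median=1e-6, n_de_mrna=0, n_de_lnc=0,
            n_shared_mrna=0, n_shared_lnc=0, module_sizes=(),
            n_scc_genes=0, n_trans_pairs=0)
        assembly, _, truth = sd.generate_annotation(3, cfg)
        samples = sd.make_samples(3, cfg)
        counts = sd.generate_counts(assembly, truth, samples, 3, cfg)
        est = size_factors(counts)
        lib = np.array([truth.library_factors[s] for s in counts.columns])
        est_n = est.values / np.exp(np.mean(np.log(est.values)))
        lib_n = lib / np.exp(np.mean(np.log(lib)))
        assert np.allclose(est_n, lib_n, rtol=0.05)

    def test_library_sizes_vary_at_least_twofold(self, synth_world):
        lib = np.array(list(synth_world["truth"].library_factors.values()))
        assert lib.max() / lib.min() >= 2.0

    def test_zero_count_violators_are_all_zero(self, synth_world):
        counts, truth = synth_world["counts"], synth_world["truth"]
        zeroed = [t for t, v in truth.violators.items() if v == "zero_count"]
        assert zeroed
        for tid in zeroed:
            assert counts.loc[tid].sum() == 0

    def test_fewer_than_two_samples_per_group_raises(self):
        cfg = sd.SyntheticConfig(group_sizes=(1, 4, 3, 3))
        assembly, _, truth = sd.generate_annotation(1, cfg)
        samples = sd.make_samples(1, cfg)
        with pytest.raises(ValueError, match="fewer than 2"):
            sd.generate_counts(assembly, truth, samples, 1, cfg)

    def test_scc_phenotype_high_in_mastitis_groups(self, synth_world):
        s_scc = [s.scc for s in synth_world["samples"] if s.group[0] == "S"]
        h_scc = [s.scc for s in synth_world["samples"] if s.group[0] == "H"]
        assert min(s_scc) > max(h_scc)


class TestQtlGwas:
    def test_planted_hits_satisfy_window(self, synth_world):
        truth, qtl = synth_world["truth"], synth_world["qtl"]
        window = synth_world["config"].window
        by_id = synth_world["assembly"].by_id()
        qtl_map = qtl.set_index("qtl_id")
        for lnc, qid in truth.planted_qtl_hits:
            t = by_id[lnc]
            q = qtl_map.loc[qid]
            assert q.chrom == t.chrom
            gap = max(0, max(t.start, int(q.start)) - min(t.end, int(q.end)))
            assert gap <= window

    def test_decoys_violate_window_for_planted_de_lncs(self, synth_world):
        truth, qtl = synth_world["truth"], synth_world["qtl"]
        window = synth_world["config"].window
        by_id = synth_world["assembly"].by_id()
        de_lnc = {f for e in truth.planted_DE.values() for f in e
                  if f in truth.true_lncRNAs}
        qtl_map = qtl.set_index("qtl_id")
        for qid in truth.decoy_qtl_ids:
            q = qtl_map.loc[qid]
            for lnc in de_lnc:
                t = by_id[lnc]
                if t.chrom != q.chrom:
                    continue
                gap = max(0, max(t.start, int(q.start)) - min(t.end, int(q.end)))
                assert gap > window

    def test_gwas_pvalues_valid_and_inflated_near_planted(self, synth_world):
        gwas, truth = synth_world["gwas"], synth_world["truth"]
        assert ((gwas["pvalue"] > 0) & (gwas["pvalue"] <= 1)).all()
        # the planted trait must contain clearly sub-uniform p-values
        sub = gwas[gwas["trait"] == truth.planted_gwas_trait]
        other = gwas[gwas["trait"] != truth.planted_gwas_trait]
        assert (sub["pvalue"] < 1e-4).sum() > (other["pvalue"] < 1e-4).sum()
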