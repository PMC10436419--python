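# lncmast

lncRNA discovery and regulatory integration for bovine transcriptomes,
built around the question of how folic-acid supplementation modulates
immunity in dairy cows with subclinical mastitis.

Subclinical mastitis is mammary inflammation with an elevated somatic
cell count (SCC > 500 ×1000 cells/mL) but no clinical symptoms. Long
noncoding RNAs (lncRNAs, transcripts ≥ 200 nt without protein-coding
capacity) are candidate regulators of the immune genes involved.
`lncmast` implements, as a tested and reusable Python pipeline, the
analysis that connects an assembled blood transcriptome of four cow
groups (SF/SC = subclinical-mastitis fed/control, HF/HC = healthy
fed/control) to candidate regulatory lncRNAs:

1. **lncRNA identification** from assembled transcripts: exons ≥ 2,
   length ≥ 200 nt, read count > 0, gffcompare class codes
   `i`/`u`/`x` (intronic/intergenic/antisense) or `=` to annotated
   lncRNAs, then a coding-potential *consensus*: a transcript is
   noncoding only if every predictor agrees — longest ORF < 300 nt,
   Fickett TESTCODE < 0.95, in-frame hexamer log-ratio < 0, logistic
   composite < 0.5, plus any user-supplied external score tables.
2. **Differential expression** per comparison (SF vs SC, HF vs HC):
   median-of-ratios normalization, negative-binomial Wald tests with
   moment dispersions shrunk 50/50 to the trend, calling at
   |log₂FC| > 1 and p < 0.05, BH-adjusted p reported alongside, and
   cross-comparison intersection of DE sets.
3. **Co-expression modules** (WGCNA-style): soft power β chosen by
   scale-free fit R² > 0.9, adjacency |cor|^β, topological overlap,
   average-linkage clustering with a modularity-scanned cut, module
   eigengenes (PC1) correlated against group indicators and SCC.
4. **Target prediction** for DE lncRNAs: *cis* genes within ±100 kb,
   *trans* genes with Pearson |R| > 0.95 and p < 0.05 within a
   comparison's samples, a simplified duplex-energy binding screen
   (ndG < −0.08), SCC regressions, and the lncRNA–gene–pathway network.
5. **QTL/GWAS integration**: overlap of DE lncRNAs with mastitis/SCC/SCS
   QTL intervals (±100 kb), and sum-based GWAS signal enrichment —
   observed Σχ² of SNP signal within gene set ± 50 kb versus a
   random-gene-set permutation null, reported as emp_p and −log₁₀(P+1).
6. **Over-representation analysis** of gene lists against GMT sets
   (hypergeometric upper tail, BH).

A first-class synthetic-data generator emulates every input with planted
ground truth (true lncRNAs, fold changes, modules, targets, QTL hits,
inflated GWAS regions), so the whole pipeline is scored end-to-end
without any external data. See `docs/methods.md` for models,
assumptions, defaults and limitations.

## Worked example

The demo generates a synthetic world, runs all stages and scores the run
against the planted truth:

```bash
lncmast demo --seed 1
```

prints (seed 1):

```json
{
  "de_fdr": 0.0898876404494382,
  "de_sensitivity": 0.9642857142857143,
  "gwas_planted_min_emp_p": 0.004975124378109453,
  "identify_precision": 1.0,
  "identify_sensitivity": 1.0,
  "module_ari": 1.0,
  "n_de_lnc_SFvsSC": 11,
  "n_lncRNAs_identified": 102,
  "qtl_decoys_excluded": 1.0,
  "qtl_hits_recovered": 0.875,
  "trans_target_recovery": 0.8333333333333334
}
```

Reading this: all 102 planted true lncRNAs were identified with no
false positives (`identify_*`); 96% of planted fold changes were
recalled with an empirical FDR of 9% under the |log₂FC| > 1, p < 0.05
rule (`de_*`; the FDR of this raw-p rule grows as the true-DE fraction
shrinks — see the methods note); the three planted co-expression modules
were recovered exactly (`module_ari`); 5 of 6 planted high-correlation
lncRNA–mRNA pairs passed the |R| > 0.95 trans screen; 7 of 8 planted
QTLs were recovered (one planted lncRNA was not called DE in this
world) and no decoy QTL beyond the ±100 kb window was reported; the
planted GWAS-inflated gene set was flagged at emp_p ≈ 0.005.

To run on real inputs:

```bash
lncmast run-all \
  --assembly-gtf assembly.gtf --reference-gtf reference.gtf \
  --fasta transcripts.fa --counts counts.tsv --samples samples.tsv \
  --qtl qtl.tsv --gwas gwas.tsv --gmt genesets.gmt \
  --outdir results --seed 7
```

Each stage writes a TSV into `--outdir` plus a `manifest.json` with
parameters and checksums; re-running with the same seed and config is
byte-identical. `lncmast simulate --outdir d --seed k` writes a complete
synthetic input set with its ground truth JSON.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full synthetic end-to-end run at the given seed — input
generation, every pipeline stage, and the ground-truth recovery metrics
printed to stdout — and writes the results JSON to `--out`.
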