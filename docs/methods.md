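# Methods

This note documents the models and procedures implemented in `lncmast`,
the assumptions behind them, the defaults that matter, and what the
synthetic-data generator does and does not establish.

## Scope and stage order

The pipeline starts from the outputs of a standard assembly workflow
(HISAT2 → StringTie → gffcompare): an assembly GTF with class codes, a
reference GTF with biotypes, transcript FASTA, a read-count matrix, and
sample metadata for the four groups (SF/SC = subclinical-mastitis cows
with/without folic-acid supplementation, HF/HC = healthy analogues; the
somatic cell count SCC, in ×1000 cells/mL, is the phenotype, with
subclinical mastitis classified at SCC > 500). Read-level processing (QC,
trimming, alignment, assembly) is out of scope. Stages run as a DAG:
identify → differential expression → co-expression modules → target
prediction → QTL/GWAS integration → over-representation analysis.

## lncRNA identification

Candidates must pass, in order:

1. **structure** — exon count ≥ 2 (waived for transcripts `=`-matched to
   reference lncRNAs, since annotated single-exon lncRNAs are real in
   cattle), length ≥ 200 nt, max per-sample read count ≥ 1. The
   conventional "read-count > 0" rule is interpreted per-sample-max and
   is configurable.
2. **class code** — gffcompare `u` (intergenic), `i` (intronic), `x`
   (antisense) are novel candidates; `=` with reference transcript biotype
   `lncRNA` are known lncRNAs; everything else is discarded with a logged
   reason.
3. **coding-potential consensus** — noncoding only if *every* enabled
   predictor agrees (set intersection, mirroring the four-tool Venn
   approach). Built-in predictors replace the external binaries
   (PLEK/CPAT/CNCI/CPC2 are not executed):
   - longest forward-frame ATG→stop ORF (stop included; ties to the
     5′-most start); noncoding iff < 300 nt;
   - Fickett TESTCODE statistic from the published position/content
     lookup tables; noncoding iff < 0.95;
   - hexamer usage: mean log₂(f_coding/f_noncoding) over the in-frame
     hexamers of the longest ORF; noncoding iff < 0. A transcript with no
     complete ORF has hexamer score 0 *by definition*; absence of an ORF
     is treated as satisfying this criterion rather than failing it.
   - a logistic composite σ(orf/150 + 4·fickett + 1.5·hexamer − b) with b
     chosen so the score is exactly 0.5 at the joint boundary
     (orf = 300, fickett = 0.95, hexamer = 0); noncoding iff < 0.5.
   Externally computed score tables, when supplied, join the intersection;
   a transcript missing from an external table counts as coding
   (conservative).

Hexamer tables are trained on `=`-matched transcripts (coding tables
in-frame on the longest-ORF region; noncoding on full lncRNA sequence)
only when each class provides ≥ 100 kb of sequence — a 4096-bin frequency
table trained on less is dominated by its pseudocounts. Below that, an
analytic default (codon-usage product model vs AT-rich i.i.d. model) is
used. Categories: `u` → lincRNA, `i` → ilncRNA, `x` → lncNAT, `=` → known.

## Differential expression

Counts are prefiltered (≥ 10 in ≥ 2 samples), normalized by
median-of-ratios size factors, and tested per comparison
(SF vs SC, HF vs HC) with a negative-binomial Wald test:

- per-feature dispersion α by the method of moments from within-group
  variances (Var(q) = μ/s + αμ² on the normalized scale), shrunk 50/50
  toward the across-feature mean. The raw moment estimates are left
  *unclipped*: under near-zero dispersion they are symmetric noise around
  zero, and clipping at zero before averaging biases the variance up and
  makes the test measurably conservative (rejection 0.033 at nominal
  0.05). The variance is floored at half the Poisson variance.
- Wald z = log2FC/se with a delta-method standard error; the reference is
  a t distribution with 4·(n_t+n_c−2) degrees of freedom — the
  half-weighted variance estimate has a quarter of the sampling variance
  of the raw moment estimate, hence ~4× its degrees of freedom by a
  Satterthwaite argument. With a normal reference the test over-rejects
  (~0.06–0.07) at n = 4 vs 4; with the t reference the null rejection
  rate sits at 0.042–0.055 across probe seeds, inside the exact binomial
  99% band.

Calling uses the strict rule |log2FC| > 1 **and raw p < 0.05** — matching
the printed per-feature values of the worked examples — with BH-adjusted
p reported alongside. This is a deliberate, documented choice; the
source criteria are ambiguous about raw vs adjusted p.

`normalized_log` is log₂(count/size-factor + 1), a monotone
variance-flattening stand-in for regularized-log normalization; the
downstream correlation thresholds are validated against this transform
on synthetic data rather than assumed transferable from another one.

**A property worth knowing:** the empirical FDR of the raw-p calling rule
depends strongly on the fraction of truly differential features. In a
matrix with a log-normal dispersion tail (σ = 0.5 around α = 0.1) at
n = 4 vs 4, features in the high-α tail produce genuine p < 0.05,
|log2FC| > 1 events at ~0.15–1% rate; pyDESeq2 under the identical
calling rule yields the same false-positive load on the same matrices.
At the field-standard benchmark fraction of 10% DE features the FDR is
≈ 0.07–0.12; at a paper-like ~1% fraction it rises to ≈ 0.15–0.18. The
recovery benchmark in the acceptance suite uses the 10% design; `run_demo`
reports the full-world value.

## Co-expression modules

Unsigned WGCNA-style network: adjacency a_ij = |cor(i,j)|^β on the
normalized log expression of protein-coding genes. β is the smallest
integer (1–20) whose connectivity distribution fits a power law with
R² > 0.9 *and negative slope* (the signed-R² convention); if none
qualifies, the best fit is used with a warning. Topological overlap
TOM_ij = (L_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij); average-linkage
hierarchical clustering on 1 − TOM. Dynamic tree cutting is approximated
deterministically: 25 candidate cut heights (quantiles of the merge
heights) are scanned and the partition with maximal weighted Newman
modularity wins; clusters below `min_module_size = 30` (the WGCNA
convention; the source does not state one) fall into "grey". Module
eigengene = first principal component of the standardized member
expression, sign-oriented so members correlate positively with it on
average; module–trait r is Pearson against group one-hots and SCC with
Student-t p (df = n − 2), flagged at p < 0.05. Module selection beyond
p < 0.05 is exposed as a ranked table, not automated.

## Target prediction

- **cis**: genes whose span is within 100 kb of the DE lncRNA span (same
  chromosome, strand ignored; spans, not TSS, anchor the window). Gap =
  max(0, max(starts) − min(ends)), 0 on overlap — this definition exactly
  reproduces the printed worked-example distances (e.g. 35,090 and
  91,642 bp). Pairs at ≤ 1 kb carry an extra flag.
- **trans**: Pearson |R| > 0.95, p < 0.05 (two-sided t transform) on the
  normalized log expression over the *comparison's own samples*
  (SF+SC: n = 8; HF+HC: n = 6); cross-cohort correlation is disabled.
- **binding screen**: an explicit simplification of LncTar. For each
  alignment offset of the target's reverse complement against the
  lncRNA, the best contiguous fully complementary stretch is scored with
  an approximate Watson–Crick nearest-neighbor stacking table (no loops,
  bulges, or dangling ends; values Turner-like but not exact). ndG =
  ΔG_min / min(sequence lengths); bound iff ndG < −0.08 (strict). The
  normalization by the shorter sequence length (LncTar's own convention)
  is deliberate: normalizing by the paired-stretch length would make any
  random pair "bound", since a short perfect run always exists. The
  screen ranks pairs; it is not thermodynamically accurate. Sequences
  are truncated to 1.5 kb in the pipeline run for cost; the screen
  refuses sequences < 20 nt.
- **SCC regression**: OLS of target-gene expression on SCC, two-sided p
  on the slope.

## QTL and GWAS integration

DE lncRNAs are screened against QTL intervals with the same ±100 kb gap
rule. Point-like QTL records (4 bp intervals occur in the source tables)
are ordinary intervals; no minimum width is imposed.

GWAS sum-based enrichment for a gene set and trait: per-SNP signal =
χ²₁ quantile at 1 − p; observed statistic = Σ signal over the *union* of
SNPs within any member gene ± 50 kb (each SNP counted once); null = the
same statistic for `n_perm` random gene sets of identical size drawn
from the expressed universe (gene-set randomization, not SNP
randomization — the source does not specify; this choice preserves the
SNP correlation structure). emp_p = (1 + #{null ≥ obs})/(1 + n_perm).
The display transform −log₁₀(P + 1) is emitted exactly as conventionally
printed (it is bounded by log₁₀2 ≈ 0.30) together with plain −log₁₀(P).
"Significant SNP" for the per-gene report defaults to p < 5×10⁻⁸,
configurable; region boundaries are closed.

## Over-representation analysis

One-sided hypergeometric upper-tail p per GMT term, BH across tested
terms; default significance padj < 0.01 for GO-style and < 0.05 for
pathway-style sets. The universe is the *expressed* gene set (prefilter
survivors), not the whole annotation — the standard ORA bias control.

## The synthetic world

The generator is the package's test bed and demo. Defaults (the stated
conditions): 3 chromosomes × 5 Mb; 300 coding genes (3–6 exons) in a
gene-dense zone; 40 intergenic, 15 intronic, 40 antisense novel lncRNAs
and 25 known lncRNAs (~20% single-exon); 15% of novel lncRNAs
deliberately violate one identification filter (single exon, < 200 nt,
zero counts, coding-like sequence). Coding sequences embed an ORF
covering ~70% of the transcript with biased codon usage; noncoding
sequences are AT-rich with every ORF ≥ 140 nt interrupted (real lncRNAs
lack long ORFs; this makes the property deterministic). Counts are
negative binomial (α log-normal around 0.1, σ = 0.5) over 14 samples
(4 SF, 4 SC, 3 HF, 3 HC — the sequenced cohort sizes), library sizes
spanning 2.1×; planted log2 effects of magnitude 2–3 (30 mRNAs + 12
lncRNAs per comparison, small shared subsets); three 50-gene modules on
a group-linked latent factor; SCC log-normal (median 600 vs 100 ×1000
cells/mL for S vs H groups, matching the > 500 classification rule) with
six SCC-linked genes; six high-correlation lncRNA–mRNA pairs for the
trans screen; QTLs planted inside the ±100 kb window of chosen DE
lncRNAs plus decoys placed beyond it; GWAS SNPs uniform except an
inflated χ² signal (z ~ N(4.5, 1)) within ±50 kb of a planted gene set.

What a green synthetic run does *not* establish: realistic linkage
disequilibrium, isoform complexity, GC/length biases of real libraries,
batch structure, or the true biology of any specific gene. It
establishes that each stage recovers exactly the structure it claims to
detect, at the stated thresholds, from data with the stated statistical
shape.

## Numerical choices and degenerate inputs

- Coordinates are 1-based inclusive everywhere inside the package.
- All randomness flows from `numpy.random.default_rng` seeded per stage
  (`[seed, stage_constant]`); identical seeds give byte-identical output
  files (checksummed in the run manifest).
- Degenerate cases: empty GTF → empty bundle; empty catalog → empty
  report; all-zero feature in one group → p = 1 with a pseudocount fold
  change; constant trait/SCC → NA or error as documented; no
  all-positive feature → total-count size factors with a warning;
  connectivity without spread → soft-threshold warning path.
- Tie-breaks: ORF ties to the 5′-most start; module-height ties to the
  lower cut height; module colors assigned by decreasing size.

## Known limitations

- The NB test is not DESeq2: no Cook's distance outlier handling, no
  fold-change shrinkage, a scalar dispersion trend rather than a fitted
  mean–dispersion curve. Parity with pyDESeq2 was verified only for the
  FDR/sensitivity operating point used here.
- The duplex screen ignores loops, bulges, G·U wobble pairing and
  intramolecular structure.
- The fixed-height modularity cut is a stand-in for dynamic tree cut and
  can merge adjacent modules on small sample counts.
- Reproducing the original catalog counts (6,582 lncRNAs etc.) requires
  the original raw data and database versions and is out of scope.
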