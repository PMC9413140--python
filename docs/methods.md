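# Methods

This note documents the models, conventions and defaults behind each stage,
the design choices made where the procedure was genuinely open, and what
the synthetic-data tests do and do not establish about real data.

## Normalization

Counts are divided by their column sum and scaled to 1e6 (CPM), then
log2(CPM + pseudocount) transformed. The column sums of the supplied table
act as library-size proxies; upstream mapped-read totals are not
reconstructed. The pseudocount defaults to 1 so that zero counts map to 0
on the log2 scale. No expression filter is applied beyond dropping genes
that are zero in every sample (a `min_cpm` filter exists but is off by
default, and re-normalizes the retained genes so columns still sum to 1e6).
Gene identifiers are matched case-sensitively as strings; no alias mapping
is attempted.

## TRA composite scoring

Per-gene z-scores use the population SD (divide by n, not n − 1): the goal
of the transform is to put all genes on a common unit scale, and either
convention would serve; population SD makes the two-sample toy cases exact
(a row `[1, 3]` maps to `[−1, +1]`). Constant genes are set to z = 0 rather
than dropped — they contribute nothing to a composite but keep the set-size
accounting stable — and are flagged in the log. Missing set genes are
dropped with coverage reported; nothing is imputed.

The composite is the mean z over the set genes, down genes negated. Because
every gene row has mean 0 across samples, any composite also has mean 0
across samples (to 1e-9), and composites are invariant under per-gene
positive affine transforms of the input.

Significance comes from a least-squares fit of the z-composite on
intercept + group + covariates (ANCOVA); with no covariates and balanced
groups this is the pooled two-sample t-test. The *fold change* reported
alongside cannot come from the z scale (z units are not log2 units), so a
parallel composite is built on mean-centered, variance-unscaled log2 CPM;
its group coefficient Δ is a log2 quantity and the fold change is 2^|Δ|
with the direction given by the sign. Both composites and both contrasts
are computed on every call. p-values are two-sided; no multiple-testing
correction is applied across gene sets (one summary row per set).

A perfectly fitting design (zero residual variance) reports the adjusted
difference with an explicit undefined-p flag rather than a number; a
covariate collinear with the group indicator is a rank-deficiency error.

## DE selection

"> k-fold" is read literally as a strict inequality |log2FC| > log2(k).
The per-gene log2FC is the group coefficient of a linear model on log2 CPM
with any covariates included — with no covariates it is exactly the
difference of group means. Genes flagged constant are excluded from the
lists. No test statistic or FDR is involved by design; the selection is a
biological-effect-size criterion. Default threshold 2.0; 1.25 is the
documented choice for low-powered designs and is exposed as a parameter.
Whether a covariate is used at the lower threshold is left to the caller
(default: none).

## Motif scanning

Matrices are parsed from TRANSFAC flat files or JASPAR PFMs (via
Biopython's `Bio.motifs`), counts row-normalized to frequencies with no
pseudocount by default (0·ln 0 := 0); a pseudocount flag exists for sparse
matrices. The information weight of position i is
ci = (100/ln 4)(Σ_b f ln f + ln 4) ∈ [0, 100], zero iff the row is uniform.

MatSim is the information-weighted similarity
Σ ci·f(i, baseᵢ) / Σ ci·max_b f(i, b); the consensus of any non-uniform
matrix scores exactly 1.0, and a fully uniform matrix has no defined score
(error). `N` bases contribute frequency 0 — they can only lower a score,
never raise an error. The vectorized scanner is pinned against a direct
evaluation of the formula over every window of random matrices (≤ 1e-12),
so any alternative similarity convention fails loudly.

Hits are counted at MatSim ≥ threshold on the promoter and its reverse
complement, overlapping hits each counting; both-strand scanning reflects
double-stranded TF binding and is exposed as a flag. Hit counts are
non-increasing in the threshold and strand-symmetric by construction.

## Promoter extraction

Coordinates are 0-based half-open throughout; BED input is standard BED6
with mandatory strand. The TSS is the 5' end of the record: index `start`
for + records; for − records the TSS base is `end − 1`, so the upstream
window is the genomic interval `[end, end + upstream)` reverse-complemented
— returned sequences always read 5'→3' toward the gene. The three default
windows are [−300, 0), [−600, 0) and [−1000, +200) around the TSS; the
first two are taken as purely upstream since nothing indicates they include
transcribed sequence. Windows are truncated at contig edges with a warning
and a per-record flag. When one gene id has several TSS records the 5'-most
on the gene strand is kept (warned). `PromoterSet.trimmed` derives shorter
windows from one wide extraction by slicing at the TSS anchor, which is
exact for records not truncated downstream.

## TFBM prevalence-ratio inference

Prevalence is total hits divided by promoter count. The "all possible
prevalence ratios" are the 9 grid variants (3 windows × 3 stringencies
0.80/0.90/0.95). The t-test runs on log2 ratios against 0 rather than raw
ratios against 1: the multiplicative scale makes the up/down swap an exact
symmetry (ratios invert, direction flips, fold and p unchanged), which raw
ratios would not satisfy. The reported fold change is 2^|mean log2 ratio|;
a negative mean is reported as a fold-down. Zero prevalence on either side
of a variant triggers a Haldane-style continuity correction — 0.5 added to
both total hit counts of that variant — keeping all 9 ratios usable; the
variant is flagged. All-equal ratios have zero variance: at ratio 1 the
p-value is 1 by convention, otherwise the fold is reported with an explicit
undefined-p flag. The 9 variants are correlated (nested windows, shared
hits), so the t-test's nominal calibration is not claimed — the simulation
suite asserts only non-explosive type I error alongside correct recovery of
planted rate ratios.

## Synthetic data

The expression generator draws gene baseline means from a log-normal
(natural-log mean 4, SD 1.5, a CPM-like scale) and counts from a negative
binomial with fixed dispersion 0.1 (var = μ + 0.1μ²) — standard bulk
RNA-seq behavior; both are exposed. Planted signed sets multiply exposed
means by 2^δ (up genes) and 2^−δ (down genes). The binary covariate is
balanced within each group (keeping the design full-rank) and multiplies a
random 10% of genes by 2^0.5 when positive, emulating a nuisance effect
such as xenograft presence. The documented default scenario mirrors the
study shape: 12,000 genes, 8 exposed vs 7 control, one covariate, and three
planted signatures — NFE2L2 up (δ = +0.6, a realistic clearly-significant
shift; only the direction was reported for this pathway), NHEJ down
(δ = −log2 1.4) and cGAS-STING down (δ = −log2 1.6).

The promoter generator emits uniform-background sequences (default 1200 bp
= −1000..+200) with Poisson(λ_arm) non-overlapping insertions of an exact
consensus, placed uniformly and re-drawn on overlap (bounded retries). The
default consensus is a 12-mer: exact-consensus insertions score MatSim 1.0,
making threshold behavior analytic, and at 12 positions the uniform
background contributes < 0.1 chance hits per promoter even at stringency
0.80, so planted prevalence ratios are not diluted toward 1 (a 10-mer
would contribute ≈ 1 background hit per promoter at 0.80 and visibly
shrink ratios). Degenerate (sub-consensus) insertions are a config option.
Promoters alternate + and − source strands so the emitted genome FASTA +
BED round-trip exercises reverse-complement extraction. The scenario's
promoter arms plant λ_up = 0.5 vs λ_dn = 1.4 (rate ratio 1/2.8), an
ISGF3-like fold-down.

What the generator does *not* emulate: gene-gene correlation, varying
library sizes, GC/length biases, real promoter base composition (CpG
islands, repeats), overlapping or clustered TSSs, and degenerate motif
matches in the background. Passing recovery tests therefore demonstrate the
estimators are correct under the stated sampling model, not that the
biological conclusions of any particular dataset are right.

## Problem sizes and numerical choices

The recovery suite uses scaled-down designs chosen to make Monte-Carlo
checks sharp yet quick: 1,000-gene matrices for composite recovery (100
replicates for the planted δ = 1 check, 500 for null calibration) and
200-promoter arms (25 replicates) for ratio recovery; the acceptance
script runs the full 12,000-gene scenario once plus 20- and 10-replicate
recovery summaries. Tolerances: composite means are zero to 1e-9;
MatSim agrees with brute force to 1e-12; recovery bands are
[0.9, 1.1] around δ = 1 and [1.7, 2.3] around a planted ratio of 2.
Sub-seeds for replicates derive from one user seed via a seeded generator,
so every number is reproducible from a single integer.

## Known limitations

- The composite fold change (centered-log2 contrast) is one reasonable
  reading of "fold change of a z-scale composite"; the z and log2
  contrasts can disagree in direction for pathological sets (both are
  reported).
- The prevalence-ratio t-test treats the 9 correlated variants as a
  sample; its p-values are anti-conservative in principle and should be
  read as the original procedure's convention, not as calibrated
  frequentist error rates.
- One promoter per gene; alternative TSSs beyond the 5'-most are ignored.
- TRANSFAC's licensed matrix library is not shipped; analyses use
  user-supplied TRANSFAC/JASPAR files or consensus-derived matrices.
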