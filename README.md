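# tratelis

Transcriptomic inference for two-group bulk RNA-seq studies of environmental
exposures: signed gene-set composite scoring (Transcriptome Representation
Analysis, TRA), fold-change-based differential expression (DE) selection,
and promoter transcription-factor binding-motif (TFBM) prevalence-ratio
analysis in the TELiS style — plus a synthetic-data generator that plants
known effects so every stage is testable by parameter recovery, with no
external downloads.

## Who it is for

Groups analyzing small-n bulk RNA-seq designs (e.g. an exposed vs control
rodent experiment with a nuisance covariate) who want to ask two questions:

1. **Is a known transcriptional program shifted?** — scored against signed
   reference gene sets such as NFE2L2 antioxidant response, DNA-repair
   pathways (NHEJ, HR, …) or cGAS-STING signaling.
2. **Which transcription factors drive the shift?** — inferred from the
   prevalence of binding motifs (e.g. ISRE/ISGF3, NF-κB) in the promoters
   of up- vs down-regulated genes.

## The statistics

**TRA composite.** For gene set *S* with up-part *U* and down-part *D*,
each gene's log2 CPM is z-scored across subjects (population SD), and the
per-subject composite is

&nbsp;&nbsp;&nbsp;&nbsp;score(j) = mean over g ∈ U ∪ D of s(g)·z(g, j),&nbsp;&nbsp; s(g) = +1 for g ∈ U, −1 for g ∈ D,

i.e. the mean z-score with down genes reverse-scored. Group differences are tested by
ANCOVA (least squares on group + covariates); the reported fold change is
2^|Δ| where Δ is the group coefficient of a parallel composite built on
mean-centered (not variance-scaled) log2 CPM.

**DE selection.** Genes are called up/down by biological effect size alone:
|adjusted log2FC| > log2(threshold), strict inequality, with the log2FC
taken as the group coefficient of a per-gene linear model (covariate-
adjusted). Default threshold 2-fold; 1.25-fold mirrors smaller studies.

**TFBM prevalence ratio.** Motif similarity follows the MatInspector
convention: with per-position information weights
ci = (100/ln 4)(Σ_b f·ln f + ln 4),

&nbsp;&nbsp;&nbsp;&nbsp;MatSim(w) = Σᵢ ci·f(i, wᵢ) / Σᵢ ci·maxᵦ f(i, b) ∈ [0, 1].

Hits (MatSim ≥ threshold, both strands) are counted in promoters of the up-
and down-regulated genes; prevalence = hits per promoter. Ratios are formed
over a 3 × 3 grid of promoter windows (−300, −600, −1000..+200 around the
TSS) and stringencies (0.80, 0.90, 0.95), and the nine log2 ratios are
tested against a null mean ratio of 1 with a one-sample t-test (df = 8).

## Worked example

```sh
tratelis simulate --seed 5 --out-dir sim
tratelis run --config config.yaml       # counts/annotations/gene_sets → out/
```

with `config.yaml`:

```yaml
counts: sim/counts.tsv
annotations: sim/annotations.tsv
gene_sets: sim/gene_sets.gmt
covariates: [xenograft]
out_dir: out
```

prints the summary table (values from this exact run; the scenario plants
NFE2L2 +0.6, NHEJ −log2 1.4, cGAS-STING −log2 1.6 on a 12,000-gene,
8 vs 7 design):

```
analysis       name  fold_change direction      p_value
     TRA     NFE2L2     1.473238        up 8.640813e-09
     TRA       NHEJ     1.361466      down 1.334560e-10
     TRA CGAS_STING     1.598195      down 4.308532e-10
```

Each row is one signed gene set: the fold change of the centered-log2
composite between groups, its direction, and the ANCOVA p-value — the
planted directions are recovered and the folds sit near the planted
1.5 / 1.4 / 1.6. The motif side runs on the scenario's promoter arms
(planted rate ratio 2.8 against the up-regulated genes):

```sh
tratelis telis --up-genes sim/up_genes.txt --dn-genes sim/dn_genes.txt \
  --tss-bed sim/tss.bed --genome sim/genome.fa --motifs motif.jaspar --out telis.json
```

which reports `fold_change 2.44, direction down, p 2.6e-09` for the toy
motif — a fold-down of the factor's activity, as planted.

The same stages are available as library functions (`tra_analysis`,
`adjusted_log2fc` + `select_de_genes`, `telis_analysis`) on pandas-backed
`ExpressionMatrix` objects; see `docs/methods.md` for the full model
description.

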