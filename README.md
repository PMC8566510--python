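# matriscope

Matrisome transcriptomics for bulk RNA-seq: a tested pipeline for
profiling extracellular-matrix (ECM) gene expression across tissues,
modeling its variation with age and sex, discovering co-expressed ECM
gene programs, and comparing normal against cancer tissue across
datasets that were never batch-corrected together.

The matrisome — the catalog of ECM and ECM-associated genes: collagens,
proteoglycans, ECM glycoproteins, and the regulators that remodel them —
has mostly been studied through proteomics, because matrix proteins are
long-lived and heavily cross-linked.  This package implements the
transcriptome-side analysis: it benchmarks how well transcripts track
proteins, and then uses transcript data (far deeper and cheaper than
proteomics) to map matrisome biology in health and disease.  It is a
library, used from Python; the `examples/` directory holds one short
script per capability.

## What it computes

- **Protein–transcript concordance** (`matriscope.proteome`): for each
  tissue and matrisome category, the Spearman ρ of paired protein and
  transcript abundances is classified *inferior / equivalent / superior*
  against a permutation null built from equally many non-matrisome pairs
  (N pairs sampled without replacement, n_perm times; two-sided empirical
  quantiles at α).
- **Normalization** (`matriscope.normalize`): median-of-ratios size
  factors; a closed-form variance-stabilizing transform (VST) for
  negative-binomial counts with dispersion trend φ(μ) = a/μ + b; quantile
  normalization with the standard tie rule; median tissue profiles (with
  brain sub-tissue collapsing) and percent-of-transcriptome category
  composition.
- **Age/sex covariate models** (`matriscope.covariates`): per-tissue,
  per-gene linear models of log2-CPM on within-tissue-standardized age
  and sex, corrected for ischemic time, Hardy scale and batch, with
  optional mean–variance precision weights; p-values pooled across
  tissues under one Benjamini–Hochberg family per covariate.
- **Co-expression programs** (`matriscope.coexpression`): high-variance
  gene filtering, average-linkage clustering on 1 − Kendall τ with a
  **τ-critical** cut (every reported cluster's mean pairwise τ must clear
  z_{1−α′/2}·sqrt(2(2n+5)/(9n(n−1))), Bonferroni over gene pairs),
  anti-correlated program pairs reported as paired sub-clusters, and the
  per-sample cluster score

      S_i = (1/J) Σ_j (x_ij − x̄_j) / median_{m: t(m)=t(i)} |x_mj − x̃_j|

  (mean-centered, tissue-MAD-scaled expression averaged over the
  cluster's genes), plus fixed-effect and subject-random-intercept
  association models and disease sample clustering.
- **Normal-vs-cancer rank change** (`matriscope.rankchange`): two-stage
  gene whitelists, joint quantile normalization of GTEx-normal /
  TCGA-normal / TCGA-cancer trios, the joined-normal reference, and
  Δrank = rank_cancer − rank_joined-normal per gene, summed across
  tissues and segmented into deciles.  Only ranks cross dataset
  boundaries, so per-dataset monotone batch distortions do not corrupt
  the statistic.  A generic per-gene Wilcoxon/Holm two-group test covers
  single-cell fibroblast validation.
- **Synthetic cohorts** (`matriscope.simulate`): seeded generators for
  all of the above — negative-binomial cohorts with planted age/sex
  effects and correlated gene blocks, paired proteomes with
  category-specific concordance, cancer trios with planted rank shifts
  under per-dataset batch distortions, and a lung-fibrosis cohort with
  two anti-correlated disease programs.

## Worked example

`python examples/cancer_rank_change.py` simulates five tissue trios with
20 genes shifted up and 20 down in cancer (2 log2 each), every dataset
carrying its own monotone batch distortion, and runs the full
rank-change pipeline:

```
TISSUE1: whitelist 398 genes
TISSUE2: whitelist 400 genes
...
top 10 genes by summed rank change (up in cancer):
  ENSG00000000107: +677.0 (planted up)
  ENSG00000000317: +665.0 (planted up)
  ...
planted-up genes in 10th summed decile: 20/20
planted-down genes in 1st summed decile: 20/20
consistency: {'top_in_top_decile': 50, 'top_cells': 50,
              'bottom_in_bottom_decile': 50, 'bottom_cells': 50}
```

A summed Δrank of +677 means that gene gained roughly 135 rank positions
per tissue in cancer relative to the joined normal reference; all 50
(top-10 gene × tissue) cells landing in the 10th decile is the
cross-tissue consistency readout.  The other examples cover proteome
concordance verdicts, tissue τ matrices and composition, age/sex scans,
adipose fibrosis-program discovery, and IPF sample clustering against
normal-lung controls.

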