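# Methods

`matriscope` analyzes extracellular-matrix (matrisome) gene expression in
bulk RNA-seq: how well transcripts track proteins, how matrisome programs
differ across tissues, age and sex, which gene programs co-express within
a tissue, and which genes shift between normal and cancer tissue when the
datasets being compared come from different consortia.  This note records
the models, the parameters that matter, the synthetic data the package is
validated on, and the design choices made where the design was open.

## Containers and identifiers

Expression travels as a genes × samples matrix with a units tag
(`raw_counts`, `vst`, `log_cpm`, `tpm`, `quantile`); mixing units is an
error rather than a warning because several stages (variance filters,
whitelist thresholds) are only meaningful on a specific scale.  Ensembl
version suffixes are stripped at read time and collisions are errors, not
merges: silent merging would corrupt joins against the matrisome catalog.
The catalog maps each gene to one division (core / associated) and one
category; the analysis gene set used throughout is the core matrisome
(collagens, proteoglycans, ECM glycoproteins) plus the ECM regulators,
excluding ECM-affiliated proteins and secreted factors.  Missing
categorical covariates become an explicit `missing` level; missing numeric
covariates exclude the sample from models needing that field — no
imputation anywhere.

## Normalization

**Size factors** are plain median-of-ratios: factor_j = median over
reference genes of count_gj / geometric-mean_g, with the reference set
being genes positive in every sample, returned unscaled.  When no such
gene exists this is an error; a pseudo-reference fallback is deliberately
not applied, because the conditions producing an empty reference set
(tiny or extremely sparse fixtures) are conditions under which the
estimator is not trustworthy.  Note the exact scaling identity is on
factor *ratios*: multiplying one sample's counts by c multiplies
factor_j/factor_k by exactly c (the geometric means absorb c^(1/n)).

**VST.** Counts divided by size factors give q; per-gene dispersions are
estimated by method of moments (φ̂ = (s² − q̄)/q̄²) and a parametric trend
φ(μ) = a/μ + b is fitted across genes by iteratively reweighted least
squares (weights 1/fitted², a gamma-family working model, with trimming
of genes whose ratio to the trend leaves [1e-4, 10]).  The fitted family
has Var(q) = (1+a)μ + bμ², whose variance-stabilizing integral is applied
in closed form:

    vst(q) = log2( (1 + a + 2bq + 2·sqrt(bq(1 + a + bq))) / (4b) ) − vst(0)

This is monotone per gene, asymptotically log2 (vst(2q) − vst(q) → 1),
and proportional to sqrt(q) in the near-Poisson regime b → 0.  If the
fitted a ≤ 0 the transform falls back to constant dispersion with a
warning; b is floored at 1e-8.  Gene-wise dispersion shrinkage is out of
scope: every downstream stage that crosses dataset boundaries is
rank-based and invariant to any per-sample monotone transform, so the
difference between this transform and a fully shrunk one cannot reach the
rank-change results.  The vst(0) shift makes zero counts map to 0; it is
one additive constant per dataset and cancels everywhere except raw
threshold values, which are documented as being on this scale.  One
consequence worth knowing: on near-Poisson data the transform is
sqrt-scale with a b-dependent overall size, so absolute thresholds such
as the whitelist's "mean normalized value > 5" presume genuinely
overdispersed (real-data-like) counts.

**Quantile normalization** pools all sample columns of the input
matrices, takes the mean of sorted columns as the reference, and assigns
each tie group the mean of the reference quantiles it spans (the de facto
standard tie rule).  Output columns share one multiset of values exactly.

**Profiles and composition.** Tissue profiles are per-tissue per-gene
medians; with brain collapsing, BRAIN is the median of the brain
sub-tissue medians (median of medians, not a pooled median, so large
sub-cohorts do not dominate).  Category composition divides each
category's summed TPM by the tissue's total TPM; it is invariant to
rescaling a tissue column, hence well defined on any TPM-proportional
profile.

## Protein–transcript concordance

For each tissue and matrisome category, the observed Spearman ρ of
protein vs transcript abundance (pairs with detectable levels on both
sides only) is placed in a null distribution built by sampling equally
many non-matrisome pairs without replacement, n_perm times.  Verdicts use
two-sided empirical quantiles at α = 0.05: superior above the 97.5%
quantile, inferior below 2.5%, equivalent otherwise — the only reading
under which "equivalent" is the typical outcome for categories matching
the background.  Each (tissue, category) gets an independent stream
derived from one global seed by hashing, so adding a category does not
perturb the others' draws.  Calibration note: the null conditions on the
finite background pool; with a background only a few times larger than
the category, the conditional quantiles are narrower than the marginal
spread of an independent draw and extreme verdicts run slightly above α.
The calibration suite therefore uses a background pool ~60× the category
size, where the rate lands within ±2% of nominal.

Tissue correlation heatmaps use Kendall τ-b between median profiles, with
leaf order from complete-linkage clustering of Euclidean distances
between rows of the 1 − τ matrix.  Category-vs-background comparisons use
a two-sided Mann-Whitney U with Benjamini-Hochberg adjustment across
categories.

## Age and sex models

Genes are pre-filtered by expression: keep a gene if its CPM reaches the
CPM equivalent of 10 counts at the median library size in at least
n_min samples (n_min = smallest design-group size) and its total count is
≥ 15.  The response is log2-CPM with a 0.5-count offset.  Within each
tissue, every gene is regressed on age (standardized within tissue, so a
coefficient is per 1 s.d. of donor age), sex (F vs M indicator), ischemic
time (numeric), Hardy scale and batch (indicator contrasts; Hardy is
treated as unordered because the 0–4 codes are not linear in severity,
and missingness is its own level).  With `weights="meanvar_trend"`,
per-observation precision weights come from a lowess-smoothed trend of
sqrt(residual s.d.) against mean log2-CPM evaluated at fitted values,
inverse fourth power — the voom recipe.  Fits are per-gene weighted least
squares with a shared design, solved batched; no empirical-Bayes
moderation of variances is applied, and the package's validation is by
recovery properties (sensitivity, FDR, sign agreement on planted effects)
rather than coefficient-level equality with a moderated fit.  P-values
from all tissues are pooled and BH-adjusted in one family per covariate;
a per-tissue family option exists but is off by default.

## Co-expression clustering and cluster scores

Genes passing mean > 5 and variance > 1.5 (adipose-style) or variance > 2
(lung/IPF-style) on the VST scale are clustered with average linkage on
1 − Kendall τ distances.  The significance threshold is

    τ_crit = z_{1−α′/2} · sqrt( 2(2n+5) / (9n(n−1)) ),   α′ = α / C(G, 2)

the normal approximation to the null of Kendall's τ at n samples,
Bonferroni-corrected over the G-choose-2 gene pairs examined.  Both α and
the correction are configurable; the formula is this package's concrete
choice for "a critical value based on the number of samples and genes".

The dendrogram cut scans candidate heights from the coarsest partition
downward and accepts the first partition in which every cluster of size
≥ 2 is *valid*: either its mean pairwise τ ≥ τ_crit, or it splits (k = 2
within its subtree) into two halves that are each internally valid and
mutually negatively correlated, in which case it is reported as a paired
anti-correlated sub-cluster (labels `Ck.1`/`Ck.2` — the fibrosis-program
pattern in adipose and lung).  Scanning finest-first is degenerate (the
all-singleton partition satisfies any bound vacuously), which is why the
scan runs coarsest-first; among valid partitions this returns the
coarsest, and singletons are discarded.  Pure-noise input returns an
empty set.

The per-sample cluster score over J genes is

    S_i = (1/J) Σ_j (x_ij − x̄_j) / median_{m : t(m)=t(i)} |x_mj − x̃_j|

with x̄_j the mean and x̃_j the median of gene j over the samples of
sample i's tissue, and the denominator the raw MAD (no 1.4826 consistency
constant — the mixed mean/median form is kept exactly as stated).  Genes
with zero MAD in a tissue are excluded there and J decremented.  By
construction the score has mean 0 within each tissue and is invariant to
per-gene affine maps with positive scale.

Association models are ordinary least squares, or a subject-level
random-intercept model (REML, via statsmodels MixedLM) when repeated
measurements per subject exist; repeated percent-area measurements are
averaged per subject only in the fixed-effect variant.  The multi-tissue
gene score averages one gene's VST expression across a listed tissue set
per subject (subjects missing a tissue are excluded and logged), and the
extreme-subject selector returns top/bottom-k subjects (overall or per
sex) de-identified and order-randomized under a seed so downstream image
scoring is blinded.  Disease sample clustering centers each gene on its
cross-sample mean and cuts a complete-linkage Euclidean tree over samples
into k groups, reporting a group × disease cross-tab.

## Normal-vs-cancer rank change

Each tissue contributes raw-count datasets GTEx-normal, TCGA-normal
(optional — absent for the tissues where adjacent-normal samples are not
usable) and TCGA-cancer.  Whitelisting is two-stage: stage 1 keeps genes
with raw-count sum strictly > 5 in *every* dataset (a gene must be
rankable everywhere); each dataset is VST-normalized over its stage-1
genes; stage 2 keeps genes with mean normalized value > 5 in *at least
one* dataset, which deliberately admits genes quiet in normal tissue but
high in cancer.  The whitelisted VST matrices are quantile-normalized
together and re-separated; per-dataset per-gene means are taken; Joined-N
is the unweighted mean of the two normal datasets' means (GTEx alone when
TCGA-normal is absent), regardless of sample counts.  Ranks ascend with
expression (average ranks on ties), so

    delta_g = rank_cancer(g) − rank_joined_normal(g)

is positive when a gene sits relatively higher in cancer.  Per-tissue
deltas are summed per gene over the tissues covering it; deciles are
equal-count bins (sizes differing by ≤ 1) on each tissue's deltas and on
the summed values, ties broken by gene id (equal-width binning exists but
is non-default); top/bottom-10 gene lists and consistency counts (how
many of their per-tissue cells sit in the extreme deciles) are reported,
with NA marking tissues where a gene is not whitelisted.

Batch robustness: ranks are a function of each dataset's own mean vector,
so deltas are *exactly* invariant to strictly monotone transforms of the
cancer dataset's means, and of every dataset's means when the normal
reference is a single dataset.  When Joined-N averages two normal
datasets, a monotone distortion of one normal feeds through the averaged
values and can flip near-tied ranks — the invariance there is
approximate, which is the honest form of the method's batch-robustness
claim.  The exact property is exposed and tested at
`rank_change_from_means`.

The generic two-group comparison (used for the cancer-associated
fibroblast check) is a per-gene two-sided Wilcoxon rank-sum — exact for
small tie-free samples, normal approximation with tie correction
otherwise — Holm-adjusted over the supplied gene list, with direction the
sign of the median difference.

## Synthetic data

All generators are pure functions of a spec plus seed and emit containers
that pass the package's own validation.  Counts are negative binomial
with Var = μ + φμ², φ per gene from a Gamma (shape 2, mean 0.1 by
default), on top of a log2-scale linear predictor: baseline ~ N(7, 1)
(≈ 130 counts), tissue effects N(0, 0.5), batch effects N(0, 0.1),
residual gene noise N(0, 0.25), lognormal library factors (σ = 0.25), and
planted age/sex effects in log2 units per standardized covariate.  Donor
covariates mirror a GTEx-like pool: two-thirds male, age ~ N(52.8, 12.9)
clipped to 20–70, subjects spanning all tissues.  Correlated blocks are
driven by a per-sample latent factor with loadings chosen through the
Gaussian-copula identity ρ = sin(πτ/2), so a target within-block Kendall
τ on the latent scale maps to a factor weight; anti-correlated programs
flip the loading sign for half the block.  Count-level noise attenuates
the realized τ below the latent target by roughly 10–20% at the default
noise levels — recovery tests therefore assert cluster membership, not
the τ value itself.

The cancer-trio generator plants ±2 log2 shifts on 20 + 20 genes drawn
from mid-expression bands (ranks 30–45% and 55–70%), so shifted genes
have rank room to move, and passes each dataset's latent log-means
through its own monotone distortion (scale 0.8–1.2, shift ±1 in log2)
before sampling — emulating cross-consortium batch shifts the rank
statistic must survive.  The lung cohort (26 + 10 normals from two
sources, 10 ventilator-injury, 8 ALI, 46 IPF) drives two anti-correlated
programs (20 and 5 genes) with a latent severity per sample (0 / 0.3 /
0.47 / 1.63 for normal / ventilator / ALI / IPF — the observed effect
ordering), amplitude ~1.8 log2 per severity unit, a small shared factor
(σ = 0.25) so the programs cohere within disease groups without competing
with the severity axis, and per-source batch offsets.

What the generators do *not* emulate: gene-length effects and GC bias,
isoform structure, realistic gene-gene correlation beyond the planted
blocks, contamination between tissues, zero-inflation, or GTEx-scale
sample and gene counts (defaults are desk scale, ≤ 5000 genes and a few
hundred samples — the problem sizes used throughout the validation
suite).  Passing tests therefore demonstrate that the implementations
recover the structures they assume, at realistic noise levels, not that
real-data effect sizes will match.

## Numerical choices and degenerate inputs

Spearman uses average ranks, Kendall is τ-b; correlations of constant
vectors return a flagged NaN with a warning.  Constant covariates are
dropped with a warning; rank-deficient designs raise an error naming the
aliased columns (greedy QR).  Tie-breaks are documented where they
matter: decile boundaries by lexicographic gene id; the dendrogram cut
takes the coarsest valid partition; cluster labels order by size.
Dispersion trend failure (a ≤ 0) falls back to constant dispersion with a
warning; an empty whitelist, an all-zero-MAD cluster, an empty variance
filter, and a missing reference-gene set are all hard errors carrying the
reason.

## Known limitations

The VST approximates (rather than reproduces) the reference tool's
transform; coefficient standard errors are unmoderated, so per-gene power
at very small n is below what a shrinkage estimator would give; the
τ_crit formula is an asymptotic normal approximation (checked against a
permutation null at n = 12 to within 0.03); the rank-change invariance is
exact only in the single-normal-reference configuration, approximate in
the dual-normal one; and all validation is on synthetic cohorts whose
generative assumptions are stated above.
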