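# Methods

This note documents the statistical models, conventions and numerical
choices behind `proteoconcord`, and what the synthetic-data tests do and do
not establish about real data.

## Data model

The central container is `QuantMatrix`: a proteins × samples matrix with an
explicit boolean observation mask and a scale flag (`raw` or `log2`). Cells
that are not observed carry NaN and no numeric meaning; raw-scale observed
intensities must be strictly positive. The scale flag is the pipeline's
ordering guard: the log2 stage refuses a log2 matrix, quantile
normalization and imputation refuse a raw one, so stages cannot be applied
out of order or twice.

DIA-NN protein-group matrices use the `diann_pg` dialect: the
`Protein.Group` column keys rows, semicolon-separated groups collapse to
their leader accession (a convention of this package — search engines do
not standardize group keys), and **zero intensities are read as missing**,
because DIA-NN writes zeros for quantities absent from a run. Generic
TSV/CSV dialects treat only empty cells and NA-like tokens as missing; a
literal zero in a generic table is a (raw-scale-invalid) value, never
silently converted.

## Preprocessing

Canonical order: valid-value filter → log2 → quantile normalization → PCA
imputation → optional cohort centering. Imputation runs *after*
normalization so the low-rank model sees distribution-matched columns; the
stages are independent transformers, so other orders are possible but not
default.

**Valid-value filter.** Two rules, matching the two analysis contexts:
`any_group` keeps a protein observed in ≥ `min_fraction` (default 0.60) of
the samples of at least one biological group (the within-study rule);
`each_cohort` keeps a protein observed in ≥ 0.35 of the samples of *every*
cohort (the cross-cohort rule). Fractions are compared with ≥, so 3/8
(0.375) passes a 0.35 threshold.

**Quantile normalization.** The reference curve is the mean over columns of
each column's empirical quantile function evaluated on a uniform grid of
`n_proteins` points; each column's observed values are mapped by
interpolating that curve at their fractional rank positions
(`linspace(0, 1, n_observed)`). On complete matrices this reduces to the
classical sort/average/restore construction and is idempotent. Ties receive
the mean of the reference quantiles their ranks span; this tie-averaging
means a tied column's sorted multiset is no longer exactly the reference
vector (the tied entries collapse to their mean, preserving the sum). The
implementation agrees with the standard R implementation to 1e-10 on both
complete and incomplete matrices (verified in the test suite via Rscript);
the only divergence is tie handling inside incomplete columns, where we
average mapped quantiles rather than interpolating at an averaged rank.
Missing cells remain missing; a column with fewer than two observed values
is an error.

**PCA imputation.** Iterative low-rank completion, the NIPALS-style
behaviour of the R `pcaMethods::pca` imputation commonly used in
proteomics: initialize missing cells at protein (row) means; iterate
(row-center the completed matrix → rank-k truncated SVD → restore row
means → overwrite missing cells only) until the largest absolute change at
a missing cell < `tol` (default 1e-6) or `max_iter` (default 500), then
warn with the final delta but still return the result. Defaults k = 2.
Observed cells are bit-identical before and after; imputed positions are
recorded on the output. Convergence is linear and can be slow on small
noisy matrices where the rank-k directions chase noise; the warning is
informative, not fatal. A deleted cell of an exactly rank-1 matrix is
recovered to 1e-6 with k = 1 (closed-form check).

**Cohort centering.** Batch correction is a *single scalar per cohort*: the
cohort's grand mean over observed cells is subtracted and the global grand
mean added back. Per-protein centering (ComBat-style or otherwise) is
deliberately out of scope: it would annihilate exactly the per-protein
cross-cohort differences the concordance analysis measures. The residual
cohort shift after centering is zero by construction up to per-protein
noise; the pipeline logs it so users can audit. With simulated shifts of
1.5 log2 units the residual is < 0.05.

**PCA scores** (QC): samples projected on the leading right singular
vectors of the protein-centered matrix, with the deterministic sign
convention that each component's largest-magnitude protein loading is
positive.

## Moderated t differential expression

Pairwise two-group contrasts on a complete log2 matrix: effect = mean
difference (group2 − group1), pooled within-group variance s²_g, df = n₁ +
n₂ − 2. The empirical-Bayes prior (d₀, s₀²) is fitted by moments on z_g =
log s²_g: under the scaled inverse-χ² hierarchy, s² is a scaled F variate,
so z has a known digamma/trigamma mean and variance; d₀ solves
trigamma(d₀/2) = excess variance of z via Newton iteration on the monotone
trigamma with a bisection fallback (tolerance 1e-8, ≤ 100 iterations; for
arguments > 1e7 the asymptotic 1/√y inverse is used directly). Zero or
negative excess variance — and the exact degenerate case of all-equal
variances, which short-circuits to the common value — gives d₀ = ∞ and
complete shrinkage. The construction reproduces R limma's `lmFit` +
`eBayes` on random fixtures (d₀, s₀², s²_post, t and p to ≤ 1e-4 relative;
verified via Rscript in the test suite).

Moderated t uses s²_post = (d₀ s₀² + df s²)/(d₀ + df) and a t reference
with df + d₀ degrees of freedom (standard normal when d₀ = ∞; d₀ = 0
recovers the ordinary pooled t). Degenerate posteriors: zero variance with
zero effect → t = 0, p = 1; zero variance with nonzero effect → p = 0 with
a warning. BH adjustment is the literal step-up q₍ᵢ₎ = min_{j≥i} m·p₍ⱼ₎/j,
re-implemented and cross-checked against both a brute-force double loop and
statsmodels. DEP calls: up/down at q < fdr (default 0.05) with the sign of
the effect; proteins removed by the filter are simply absent from m.

A `moderate=False` flag gives plain pooled-t statistics for users who want
the unmoderated screen; BH is still applied.

## Concordance (GSI)

Per cohort pair, the per-protein cohort means m_A, m_B feed five
statistics. Pearson r and ICC are **global** — one number each, computed
across proteins on (m_A, m_B) and shared by every protein — because a
per-protein correlation across two cohorts is undefined; percent
similarity, percent difference and the Bland–Altman Z are per protein. The
ICC variant is ICC(2,1) (two-way random effects, absolute agreement, single
rater) with proteins as subjects and cohorts as raters, so a constant
cross-cohort offset lowers it; it matches pingouin's ICC(A,1) and a
brute-force two-way ANOVA in tests. Percent similarity is
100·(1 − |m_A − m_B| / pair mean), clamped to [0, 100], computed on
log2-scale means (the scale the rest of the analysis lives on).

Bland–Altman: d_g = m_A − m_B, bias = mean(d), limits of agreement =
bias ± 1.96·sd(d), z_g = (d_g − bias)/sd(d), flags at |z| > 1.96. When
sd(d) = 0 (self-comparison) every z is defined as 0 and nothing is
flagged, so a cohort compared with itself scores exactly 1.

Component normalizations onto [0, 1] are this package's constructions (the
weighted-average design fixes weights, not normalizations): c1 = (r + 1)/2,
c2 = max(0, ICC), c3 = psim/100, c4 = 1 − min(pdiff, 100)/100, c5 =
max(0, 1 − |z|/1.96). GSI_g = 0.25c1 + 0.25c2 + 0.20c3 + 0.15c4 + 0.15c5;
the global GSI is the mean over proteins. Categories: very high ≥ 0.90,
high ≥ 0.75, moderate ≥ 0.50, low otherwise — named bins exist in the
design, the cut-offs are our convention. Note that because z is
standardized, c5 has mean ≈ 0.54 under pure noise regardless of the noise
scale; the GSI therefore saturates near ≈ 0.93, not 1.0, for two
independent noisy replicates of the same cohort, and equals exactly 1.0
only for exact duplication. Both the mean percent similarity and the
global GSI are reported, labelled distinctly.

## Stratified cross-validation

Samples are dealt round-robin to k folds (default 4, k < 3 rejected) after
a seeded shuffle within each (cohort, group) stratum, so within-stratum
fold sizes differ by at most one (58 → 15/15/14/14, 8 → 2/2/2/2). Folds
partition *samples*; partitioning proteins was the other reading of the
design and is noted as an alternative, not implemented. Per protein and
fold, the cross-cohort mean difference is computed on the training
complement (d_train) and the held-out fold (d_test);

- corr_g = Pearson over the k (d_train, d_test) pairs (for null proteins
  this is typically negative, since a fold's deviation is anti-correlated
  with its complement's);
- stability_g = 1 − sd(d_test)/(|mean(d_test)| + ε), clamped to [0, 1],
  ε = 1e-8; when both sd and |mean| < ε the protein is perfectly stable at
  zero (stability 1), while a noise-dominated protein (mean ≈ 0, sd > 0)
  scores 0;
- composite_g = 0.5·(corr_g + 1)/2 + 0.5·stability_g, our equal weighting
  of the two ingredients; ranking is by descending composite with
  lexicographic protein-id tie-break.

## Synthetic data

The generator emulates the two-center study design: cohorts of configurable
size (defaults 8 and 58) and groups, ~10³–10⁴ proteins with per-protein
log2 baselines ~ Normal(20, 2), within-protein residual sd 0.5, a
configurable DEP fraction with symmetric ±effect on the affected group, a
scalar cohort batch shift, and missingness with probability
mcar + (1 − mcar)·logistic(−steepness·(x − midpoint)) in log2 abundance x.
The default midpoint is −∞, which switches the logistic (MNAR) term off
entirely; a finite midpoint with steepness 0 leaves it at 1/2. Matrices
are emitted on the raw scale with a full mask so the pipeline's own log2
and filtering are exercised. All randomness flows from one seed through
two fixed sub-streams (cohort simulation; missingness injection), so
outputs are bit-reproducible.

What the simulation does *not* model: protein–protein correlation,
intensity-dependent variance, peptide-level effects, per-protein batch
interactions, or real annotation structure. Passing tests therefore
establish the pipeline's internal correctness and calibration under an
idealized independent log-normal model — not that any particular pair of
real cohorts will score a given GSI.

## Problem sizes and determinism

The test and acceptance runs use deliberately desk-scale problems — 10³–10⁴
proteins, tens of samples — where every check completes in seconds: prior
recovery on 5000 simulated variances, type-I calibration on 2000 null
proteins at 8 vs 8, DEP recovery on 1000 proteins at 10 vs 10 (realized
FDP ≤ 0.10, recall ≥ 0.8 at effect = 2·residual sd), Bland–Altman flag
calibration on 10⁴ normal differences, and a 500 × 10 self-comparison for
the GSI identity. All stochastic tests fix seeds; the pipeline's global
seed fans out to per-stage seeds by fixed offsets, and rerunning a config
reproduces identical artifacts.

## Known limitations

- The GSI normalizations and category cut-offs are conventions; alternative
  choices rescale scores and shift category counts.
- Scalar cohort centering removes only a global batch offset; per-protein
  batch effects pass through (by design, see above) and would depress the
  GSI.
- Quantile normalization assumes columns share a common intensity
  distribution; group-dominant global shifts would be flattened.
- The moderated-t path assumes a complete (imputed) matrix; variance
  estimates do not propagate imputation uncertainty.
- MNAR imputation by low-rank completion biases imputed values toward row
  means, which can inflate DEP calls slightly when missingness is strongly
  abundance-dependent (visible in the demo's tallies).
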