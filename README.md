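# proteoconcord

Cross-cohort concordance analysis for label-free DIA proteomics.

When two centers profile the same disease — here the motivating setting is
adrenocortical neoplasia (normal adrenal, adenoma, carcinoma, macronodular
hyperplasia) quantified by DIA mass spectrometry at two hospitals of very
different cohort size (8 vs 58 samples) — the question is whether their
protein-quantification matrices actually agree well enough to validate each
other's differentially expressed proteins. `proteoconcord` implements the
quantitative core of that comparison as a tested, reproducible pipeline:

1. **Preprocessing** of protein-group matrices (DIA-NN `pg_matrix` dialect or
   generic TSV/CSV): valid-value filtering (≥ 60% observed in at least one
   biological group, or ≥ 35% observed in every cohort), log2 transform,
   quantile normalization (with fractional-rank interpolation under
   missingness), iterative low-rank PCA imputation, and scalar per-cohort
   batch centering.
2. **Differential expression** by the moderated t-statistic: per-protein
   pooled variances s²_g with df_g degrees of freedom are shrunk toward a
   scaled inverse-χ² prior (d₀, s₀²) fitted across proteins by moments on
   log-variances,

   s²_post = (d₀·s₀² + df·s²)/(d₀ + df),  t = Δ̄/√(s²_post·(1/n₁+1/n₂)),

   with two-sided p-values on df + d₀ degrees of freedom,
   Benjamini–Hochberg FDR, and signed DEP calls at q < 0.05.
3. **Concordance scoring** via a weighted Global Similarity Index (GSI) on
   [0, 1] per protein: Pearson correlation (25%) and ICC(2,1) (25%) computed
   globally on the two cohort-mean vectors, plus per-protein percent
   similarity (20%), Bland–Altman percent difference (15%) and a
   standardized Z-score penalty (15%, vanishing at |z| = 1.96). Proteins are
   binned as very high (≥ 0.90), high (≥ 0.75), moderate (≥ 0.50) or low
   similarity; the Bland–Altman analysis reports bias, 1.96·sd limits of
   agreement and per-protein flags at |z| > 1.96.
4. **Robustness scoring** by stratified 4-fold cross-validation: per protein,
   the cross-cohort mean difference is estimated on the training and test
   samples of each fold; a composite of train/test correlation and
   fold-to-fold stability ranks proteins by how consistently their
   cross-cohort behaviour replicates.

A synthetic-data module generates two-cohort, two-group data with known
ground truth (log-normal abundances, signed DEP effects, a scalar cohort
batch shift, MCAR + abundance-dependent MNAR missingness), so every stage is
testable without access to the original deposits.

The stages are scikit-learn-style estimators (`ValidFractionFilter`,
`QuantileNormalizer`, `PCAImputer`, `CohortCenterer`, `ModeratedTTest`,
`CohortConcordance`, `ConcordanceCrossValidator`) with functional wrappers,
plus a `proteoconcord` CLI.

## Worked example

Run the packaged synthetic demo (800 proteins; cohorts USP and SNUH with
NHA/ACC groups of 5+8 and 8+12 samples; 10% DEPs at 1.0 log2 effect; a 0.5
log2 batch shift; mixed MCAR/MNAR missingness):

```sh
proteoconcord run --out-dir demo_out
```

which prints (abridged):

```json
{
  "concordance": {
    "categories": {"very_high": 629, "high": 169, "moderate": 0, "low": 0},
    "global_gsi": 0.9371724488212586,
    "global_similarity_pct": 99.34511817074787,
    "icc": 0.9964033278554166,
    "pearson": 0.9964085708399583,
    "mean_d": 3.873259273880245e-16,
    "loa": [-0.32738149463588145, 0.32738149463588223]
  },
  "contrasts": {
    "ACC_vs_NHA": {"n_up": 52, "n_down": 43,
                   "d0": 26.84221288515985, "s0_sq": 0.21427901246303188}
  },
  "n_proteins_input": 800,
  "n_proteins_kept": 798
}
```

Reading this: after the 35%-per-cohort filter, 798 proteins survive. The two
cohorts agree closely — Pearson and ICC ≈ 0.996 across cohort means, mean
percent similarity 99.3%, Bland–Altman bias ≈ 0 with limits of agreement
±0.33 log2 units, and 629/798 proteins score "very high" GSI — because the
injected batch shift was removed by cohort centering. The ACC-vs-NHA
contrast calls 95 DEPs (52 up, 43 down) against 80 injected ones, with the
variance prior fitted at d₀ ≈ 26.8, s₀² ≈ 0.21. Per-protein tables
(`concordance.tsv`, `dea_ACC_vs_NHA.tsv`, `crossval.tsv`), the fold plan,
the echoed config and a run log land in `demo_out/`; rerunning with the same
seed reproduces every byte.

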