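# Methods

This document describes the statistical methods implemented in `metabosel`,
the parameter defaults and their rationale, the synthetic-data generator, and
the numerical choices that make results exactly reproducible.

## 1. Data model and assumptions

The unit of analysis is a **feature table**: intensities for *p* LC-MS
features across *n* samples, with sample metadata assigning each sample to
exactly one of two study groups or to the pooled-QC class. Assumptions:

- Intensities are non-negative; zero and NaN both denote "not detected"
  (a configurable sentinel maps zeros to missing on import).
- Pooled QC injections are technical replicates of the same material, so
  their variation estimates analytical (not biological) noise.
- After log transformation, group differences are approximately location
  shifts; the univariate test battery falls back to Mann-Whitney when
  normality or variance homogeneity fails.
- Exactly two study groups. Multi-class designs are out of scope.

## 2. Quality-assurance filtration

Features are removed, in order, by three rules (each rule sees the survivors
of the previous one; the per-stage log records counts and removed ids):

1. **QC presence** — detected (non-missing and > 0) in ≥ 50 % of QC
   injections. A feature the QC cannot see cannot be quality-assessed.
2. **QC repeatability** — coefficient of variation across detected QC values
   (raw scale, sd/mean with the n−1 denominator) strictly < 20 %. Features
   with fewer than two detected QC values are removed (CV undefined).
3. **Group presence** — detected in ≥ 80 % of the samples of at least one
   study group, so a feature consistently present in one group survives even
   if absent in the other (a biologically meaningful on/off pattern).

Boundary conventions are part of the contract: presence fractions exactly at
50 % / 80 % are kept; a CV of exactly 20 % is removed. Missing values in
surviving features are imputed with **half the per-feature minimum** observed
value, the conventional stand-in for below-detection-limit censoring.

## 3. Scaling

Fitted on study samples only (QCs excluded), on log-transformed data:

- **UV (unit variance)**: (x − mean) / sd. Every feature gets equal a-priori
  weight, which favours low-abundance, low-variance features.
- **Pareto**: (x − mean) / sqrt(sd). A compromise that partially retains
  magnitude information and damps noise inflation.

Standard deviations use the n−1 denominator. Zero-variance columns are an
error (the caller must filter them), never silently dropped.

## 4. OPLS-DA and VIP

The Trygg-Wold orthogonal-signal-correction recursion (see README for the
update equations) removes *K* Y-orthogonal components from X, then fits one
predictive PLS component against the centered ±1 class code. Defaults:
`n_orth = 1` (the usual choice for a two-class model; additional components
are fitted only if orthogonal variation remains), VIP threshold 1 (strict
inequality; since mean(VIP²) = 1, VIP > 1 means "above-average influence").

- **R²Y** = 1 − residual SS / total SS of the class code.
- **Q²** = 1 − PRESS/SS under stratified 7-fold cross-validation
  (`k = 7` default). Inside each fold the scaler is re-fitted on the training
  samples (no leakage) and test data are OSC-deflated with the training
  model's orthogonal loadings before prediction.
- **Hotelling T²** outlier screen (optional, off by default): PCA on the
  scaled study matrix, flagging samples with
  T² > A(n−1)(n+1)/(n(n−A)) · F⁻¹(0.95; A, n−A), A = 2 components.
  QC samples are never dropped.

## 5. Univariate testing and BH-FDR

Per feature, the two-group test is chosen by a fixed gate: Shapiro-Wilk on
each group (α = 0.05); if both normal, Brown-Forsythe (median-centered
Levene) decides Student vs Welch *t*; otherwise Mann-Whitney (exact for small
tie-free samples, asymptotic with tie correction otherwise). Groups with
fewer than 3 observations skip Shapiro-Wilk and use Mann-Whitney. P-values
are adjusted by the Benjamini-Hochberg step-up:
q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ (p₍ⱼ₎ · m / j), capped at 1. Selection is strict: q < 0.05.

In the FDR-filtered OPLS approach, OPLS-DA + VIP > 1 is then fitted on the
q-significant subset only. An empty pre-selection short-circuits with a
warning; a singleton pre-selection is returned as-is (a one-feature
projection model is meaningless).

## 6. LASSO logistic regression

Objective (no 1/n factor, unpenalized intercept β₀):

```
g(β₀, β) = Σᵢ [ log(1 + exp(ηᵢ)) − yᵢ ηᵢ ] + λ Σⱼ |βⱼ| ,   η = β₀ + Xβ
```

on column-standardized X (n−1 denominator) and y ∈ {0, 1} assigned by
lexicographic group order. Solved by IRLS with cyclic coordinate descent and
soft-thresholding, with glmnet-style active-set sweeps between full passes
and warm starts along a decreasing λ grid.

Numerical details that matter:

- The working residual uses the **exact** probabilities π, so the stationary
  point satisfies the true KKT conditions (verified to < 1e−6 in the tests);
  only the curvature weights π(1 − π) are floored at 1e−5, which bounds step
  sizes near separation without biasing the gradient.
- A descent safeguard halves any IRLS step that increases the true penalized
  objective (IRLS is not guaranteed monotone).
- Coefficients with |β| ≤ 1e−12 are snapped to exactly zero so "active set"
  is well defined at the λ_max boundary.

λ grid: 100 logarithmically spaced points from
λ_max = maxⱼ |xⱼᵀ(y − ȳ)| (the smallest λ with an empty model) down to
10⁻³ λ_max. λ is chosen by **AIC** = −2ℓ + 2(df + 1) with df = |active set|
(ties broken toward the larger λ, i.e. the sparser model), or optionally by
5-fold cross-validated deviance (`rule="cv_deviance"`), with per-fold
re-standardization.

**Bootstrap reproducibility**: 1000 stratified with-replacement resamples
(group proportions preserved); each resample is re-standardized and λ is
re-tuned before refitting, so the score reflects the whole selection
procedure, not just the final fit. A feature's reproducibility is the
percentage of resamples in which it was active. Features constant within a
resample are excluded from that resample's model and counted as unselected.
The default report flags selected features below 90 % reproducibility.

## 7. Synthetic-data generator

`SimulationDesign` defaults describe the reference study: 50 + 50 study
samples, 8 pooled QCs, 500 features, 10 planted differences at
|log2 fold change| = 1 (random sign), biological CV 30 %, QC (analytical)
CV 15 %, block-correlated features (blocks of 10, within-block correlation
0.6), limit-of-detection censoring at each feature's 5 % abundance quantile.

Generation is in log2 space: baselines ~ N(18, 2); per-sample deviations are
a block factor model (√ρ · block factor + √(1−ρ) · idiosyncratic) scaled to
the target biological sd; QC intensities are the log of the mean raw
expectation plus analytical noise; censored values become missing.
`true_baseline_quantile` optionally plants the true features at low baselines
(low raw variance) to probe the UV-vs-Pareto contrast. Ground truth (ids and
signed effects) is returned alongside the table, and `truth_metrics` computes
recall / precision / false-discovery proportion of any selection.

Scope: the generator reproduces the *statistical* structure a selection
method faces (correlation, heteroscedastic noise, censoring, QC replication).
It does not model retention-time drift, batch effects, adduct/isotope
redundancy, or matrix effects — conclusions about those phenomena are out of
scope.

## 8. Workflow, comparison, and determinism

`run_all` executes: QA filtration → half-minimum imputation → (optional)
outlier removal → OPLS-VIP under UV and Pareto → FDR-filtered OPLS under both
scalings → LASSO + bootstrap. The three-way Venn comparison (7 region counts
keyed "100" … "111") uses the UV selections of the two OPLS approaches and
the LASSO selection; the consensus is their triple intersection. Outputs:
one TSV per approach (with reproducibility for LASSO), `report.json`,
`qa_filter_log.jsonl`, `outliers_removed.json`.

Determinism: all randomness flows from `numpy.random.default_rng(seed)`
(bootstrap child seeds drawn below 2³¹; CV folds via scikit-learn's
`StratifiedKFold(shuffle=True, random_state=seed)`), so a config + seed
yields byte-identical output files across runs — this is asserted in the
test suite.

## 9. Open design decisions

- **Scaling for LASSO**: the penalized model always uses UV standardization
  (the penalty is only meaningful on a common scale); the UV/Pareto contrast
  applies to the projection methods.
- **AIC over BIC**: AIC favours slightly larger models; with the bootstrap
  stability filter on top, liberal λ selection is corrected downstream.
- **Strict thresholds** (VIP > 1, q < 0.05, CV < 20 %): boundary values fall
  on the conservative side for selection rules and the permissive side for
  presence rules, and are covered by explicit boundary tests.
- **Per-resample re-tuning** in the bootstrap is costlier than refitting at a
  fixed λ but measures the stability of the full procedure.

## 10. Limitations

- Two groups only; no covariate adjustment, no paired designs.
- One predictive OPLS component (adequate for two classes; multi-component
  Y is not supported).
- AIC uses the active-set size as degrees of freedom — exact for the LASSO
  under orthogonality, approximate otherwise.
- Bootstrap reproducibility is a stability measure, not a selection-error
  guarantee; features with correlated blocks share and split reproducibility.
- The generator's known-truth recall/precision quantify behaviour on
  synthetic structure, not on any particular real instrument's data.
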