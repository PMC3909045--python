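# Methods

This note records the models and procedures implemented in `inktqsar`, the
assumptions behind them, and the design choices made where the literature
convention is silent.

## Data model

A raw measurement is one row: compound, study, test-system, marker,
dose/time condition, and a non-negative response value in study-specific
units. The closed vocabularies are the five test-systems (species ×
in-vivo/in-vitro × cell-cell/cell-plate presentation) and four cytokine
markers (IL-2, IFN-γ, IL-4, IL-13), giving at most 20 aggregated responses
per compound. The two cell-plate systems are ingested and summarised but
excluded from desirability axes and modelling by default: plate-bound CD1d
assays are rare and poorly comparable with the cell-cell systems.

## Normalisation and aggregation

Cross-study comparability rests on one assumption: the within-study ratio
of an analogue's response to the α-GalCer reference is unit-free and
approximately stable across laboratories. Within each (study, test-system,
marker) we keep only the dose/time condition at which the *reference* is
maximal (ties break to the lowest dose, then the earliest time — a
deterministic, conservative rule), divide analogue responses by the
reference response there, and drop the cell when the reference reads zero
(the ratio is undefined; no imputation). Replicates from different studies
are averaged on the ratio scale with equal weights — replicate counts per
cell are typically 1–4, too few for variance weighting to be reliable.
When research groups used different dose grids, selection happens per
study first and averaging after.

## Desirability scoring

Each relative response y is transformed linearly to d ∈ [0.1, 0.9]:

    larger-better   d = 0.1 + 0.8 (y − Y_lo)/(Y_hi − Y_lo)
    smaller-better  d = 0.9 − 0.8 (y − Y_lo)/(Y_hi − Y_lo)

clipped at the range ends. Anchors default to Y_lo = 0 and Y_hi = the
maximum response observed per (in-vivo/in-vitro group, marker) — the
"maximally found response" convention — and are overridable. Values above
Y_hi clip to 0.9 rather than raising: a newly tested compound may
legitimately exceed the historical maximum. Overall desirability is the
geometric mean of its components, which penalises inconsistent profiles
(0.1 with 0.9 gives 0.3) and stays within [0.1, 0.9].

Axis composition: Th1 = IFN-γ larger-better + IL-4 smaller-better, Th2
mirrored. IL-2 and IL-13 are excluded from axes by default (IFN-γ and IL-4
are the canonical polarization pair and by far the best covered); a config
flag adds IL-13 (larger-better) to the Th2 axes. In-vitro axes use the
mean of the human and mice cell-cell responses per compound — the two
assays rank compounds very similarly, and pooling roughly doubles the
modelling sample — taking whichever is available when only one exists. An
axis D is missing whenever any required component is missing.

## Chemical space

Descriptor columns with variance ≤ 1e-12 are removed (bulk-computed
descriptor sets contain many constants; the tolerance absorbs float
noise). The matrix is autoscaled (unit variance, the chemometrics
convention) unless disabled. PCA is computed by SVD of the scaled matrix —
numerically stabler than eigendecomposition of the covariance — with a
deterministic sign convention (largest-magnitude loading per component
positive) so scores are reproducible across BLAS builds. Clustering is
agglomerative with average linkage (UPGMA) on Euclidean distances of the
scaled matrix; squared-Euclidean is available. The distance/scaling
choices for clustering are declared defaults, not field standards — there
is no single convention — and are isolated behind one function.

## Test-model variability

Intra-variability: per-compound RSD (%) across replicate normalized
values, sample (n−1) standard deviation (replicate counts are small),
compounds with fewer than two replicates or zero mean excluded.
Inter-variability corrected for method noise:

    RSD_inter = 100 · sqrt(max(0, s²_between − mean s²_intra)) / grand mean

where s²_between is the variance of per-compound means and s²_intra the
average within-compound variance over replicated compounds. The correction
formula is one defensible reading of "corrected for the intrinsic
intra-variability"; it floors at zero and is deliberately confined to a
single replaceable operation. Group comparisons use Kruskal–Wallis with
tie correction (χ² p-values, df = groups − 1; a fully degenerate input
returns H = 0, p = 1), and cross-model agreement uses Spearman mid-rank
correlation on complete-case compound means.

## Structure–immune models

Descriptors are autoscaled inside every fit and the scaling parameters are
stored with the model, so prediction on new compounds applies the training
transformation. Complete-case rows per axis; no imputation of missing D.

**Stepwise MLR.** Forward steps add the candidate with the smallest
partial-F probability, backward steps remove any included descriptor whose
partial-F probability exceeds p_remove = 0.10, iterating to a fixed point
with ties broken by column order and rank-deficient additions skipped.
Because a forward step scans m candidates, comparing the *minimum* of m
p-values against p_enter = 0.05 would admit a noise descriptor in
≈ 1 − 0.95^m of steps — 40% at m = 10 — so the default entry rule
Bonferroni-adjusts the minimum (min-p × m < p_enter), holding the per-step
false-entry rate at p_enter. This is the package's design choice;
`adjust="none"` restores the classical per-candidate convention of
legacy statistics packages.

**PLS.** NIPALS-style latent-component regression (via scikit-learn) on
autoscaled descriptors, coefficients back-transformed to input scale; with
as many components as the rank of X it reproduces ordinary least squares.
The component count is chosen by k-fold Q², stopping when an extra
component improves Q² by less than 0.01 — commercial chemometrics tools
each have their own significance rule, so this one is explicit and
configurable.

**Cross-validation.** Q² = 1 − PRESS/SS_tot with seven folds by default,
each fold predicted from a model fit on the remainder, SS_tot about the
full-data mean, and fold assignment a deterministic shuffle per seed. For
stepwise MLR the *entire selection procedure* is re-run inside each fold;
cross-validating only the final refit would be optimistically biased.

## Evaluation

Strong ⇔ D strictly greater than the reference compound's D (the reference
itself is weak). AUC uses the mid-rank Mann–Whitney formulation; the ROC
curve is a threshold sweep anchored at (0,0) and (1,1). By default ROC
scores are fitted values (a goodness-of-fit view); out-of-fold
cross-validated predictions are available via config since the fitted-value
AUC flatters the model.

## Synthetic-data generator

The generator emulates a literature-aggregated dataset with known truth:

* Descriptor matrix: an informative block sharing one latent factor
  (pairwise correlation = `block_correlation`, default 0.7 — bulk
  descriptor sets are strongly collinear), independent nuisance columns,
  and `n_constant` constant columns. The reference compound's informative
  descriptors are zeroed so its expected relative response is exactly 1.
* Responses: raw value = exp(x·β) × baseline × dose-profile × lognormal
  noise, with one noise draw per (study, analogue) applied to the
  analogue/reference ratio (cytokine concentrations are positive and the
  analysis works on ratios, so multiplicative noise on the ratio scale is
  the natural model; the reference is the within-study unit and carries no
  separate noise term). `study_noise_cv` defaults to 0.5 — inter-laboratory
  cytokine assays commonly disagree by ~50%. Three doses per study with a
  peaked reference dose-response exercise the condition-selection rule.
  Measurement sparsity follows `measure_prob`, per cell or global.
* Polarity: IL-4 coefficients are the negation of the IFN-γ pattern
  (IL-13 follows IL-4 and IL-2 follows IFN-γ at half magnitude), so
  compounds at the extremes of the informative axis are genuine Th1 or Th2
  polarizers and the strong/weak ROC task is non-trivial.

What the generator does *not* emulate: real dose–response shapes and
pharmacokinetics, assay-specific biases between test-systems, non-linear
structure–activity relations, and the heavy-tailed, curated messiness of
literature data. Passing tests therefore demonstrate correctness of the
computations and recoverability under the stated noise model, not
field performance on real datasets.

`coefficient_scale_for_r2` calibrates the coefficient magnitude for a
target log-scale R², using signal variance c²k(1 + ρ(k−1)) for k equal
positive coefficients on an equicorrelated block and residual variance
ln(1 + cv²/m) after averaging m replicates.

### Benchmark conditions

The parameter-recovery benchmark (`recovery_benchmark_config`) uses 150
compounds × 50 descriptors, 5 informative, single study per cell, cv = 0.5,
coefficients calibrated for R² ≈ 0.8, and an informative-block correlation
of 0.3. The lower correlation is deliberate: at ρ = 0.7 the fifth
informative descriptor's unique contribution gives an expected partial
F ≈ 11.6 against an entry threshold of F ≈ 11.1 (p_enter = 0.05 after
Bonferroni over 50 candidates), so no variable-selection rule with per-step
family-wise control can reliably separate it from noise — reliable recovery
is then information-theoretically out of reach, not an algorithmic matter.
At ρ = 0.3 the expected partial F is ≈ 44 and recovery is robust. The
response regressed in the benchmark is the log aggregated relative
response, which is linear in the true coefficients by construction.

## Numerical notes and limitations

* All randomness flows through explicit integer seeds; pipeline runs with
  identical config and inputs produce byte-identical artifacts.
* Frequency percentages are reported to two decimals and sum to 100 within
  ±0.05 rounding slack.
* Degenerate inputs fail loudly: empty frequency input, all-constant
  descriptor matrices, zero-variance responses, single-class ROC labels
  and sub-minimum sample sizes raise with context rather than returning
  silent NaNs; recoverable oddities (missing reference in a study, zero
  reference response, unscoreable axes) warn and skip.
* The pipeline's default problem sizes (tens of compounds, tens of
  descriptors in examples and fixtures; 150 × 50 in the benchmark) keep
  every analysis interactive on a single core; all stages scale to
  hundreds of compounds and thousands of descriptors without structural
  change.
* Only linear one-sided desirability transforms are provided; the general
  Derringer family (two-sided, power-shaped) is out of scope, as are
  automatic cluster-count selection, inverse-variance replicate weighting,
  outlier rejection, and confidence intervals on AUC.
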