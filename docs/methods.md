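# Methods

## Study design and estimands

The package analyses a factorial field design for distylous plants: plants of
each population and floral morph (L = long-styled, S = short-styled) are
randomized between open pollination (C) and supplemental hand pollination
(HP). Female fitness W is total seed production (fruits x seeds per fruit).
Three estimands are computed per stratum:

1. **Directional selection gradients.** Within each population x morph x
   treatment stratum, traits are standardized to mean 0 and sample variance 1
   (n−1 divisor) and fitness is relativized by the stratum mean, both on the
   untransformed data. The gradient vector β is the OLS coefficient vector of
   w on the five standardized traits. β_i is the change in relative fitness
   per standard deviation of trait i, holding the other traits fixed.
2. **Pollinator-mediated selection.** Δβ_poll = β_C − β_HP per trait and
   population x morph. Because hand pollination removes pollen-receipt
   variation, the contrast isolates the component of directional selection
   generated by pollinators.
3. **Pollen limitation.** PL = 1 − W̄_C / W̄_HP per population x morph: the
   proportional seed-set deficit under natural pollination.

## Gradient estimation and diagnostics

OLS is computed by QR decomposition; standard errors are
sqrt(σ̂² diag((XᵀX)⁻¹)) with σ̂² = RSS / (n − p), and coefficient tests are
two-sided t tests on the residual df. No multiple-testing correction is
applied: raw per-trait p-values are reported and annotation thresholds
(0.05 significant, 0.1 marginal) live in the reporting layer.

Correlational selection terms (pairwise products of standardized traits,
γ_ij; quadratic self-terms are not offered) can be appended via
`include_cross_products`. The default pipeline path is linear-only: in
practice cross-product terms inflate VIFs past the conventional drop
threshold of 10, while the five linear terms screen clean (VIF < 1.7 under
the default generator). VIF_j = 1/(1 − R²_j) from regressing predictor j on
the others with intercept; perfect collinearity reports as infinite VIF
rather than an exception.

Strata with fewer than 8 records are refused rather than fit.

## The Δβ significance test and its identity

For each population x morph, a single model pools both arms with traits
standardized and fitness relativized *within each arm*, and contains the
five traits, a pollination dummy, and all trait x pollination products, with
HP as the reference level. Because the model is saturated in treatment, its
fit decomposes into the two per-arm fits, so the trait x pollination
coefficient equals β_C − β_HP *exactly*; its t test is the reported p-value
for Δβ_poll. The test suite asserts this identity to 1e-10 — it is what
justifies reporting the two-step subtraction alongside a model-based test.

## Pooled ANCOVA models

Model A uses C-arm data with blocks {traits, population, morph,
trait x population, trait x morph, trait x population x morph}; Model B uses
both arms and adds pollination plus every pollination interaction up to
trait x population x morph x pollination. With 4 populations these models
have 45 and 86 parameters; at the built-in cell sizes the residual dfs are
694 and 1399. Responses and covariates enter after within-stratum
standardization/relativization, so stratum intercept differences are absent
by construction and the interaction blocks carry the slope contrasts.

Each block is tested by a nested-model F test,
F = ((RSS_r − RSS_f)/(df_r − df_f)) / (RSS_f/df_f). The default is marginal
(drop one block from the full model, Type-III-like), chosen because each
interaction is interpreted in a model containing all the others; sequential
(Type-I) testing is available via `test_type="sequential"`, with the
denominator always taken from the full model. Per-trait single-column
sub-block tests (e.g. one trait's trait x morph column, df_num = 1) are
emitted alongside the block tests, matching how per-trait F statistics are
conventionally reported. If a fit is saturated (zero residual), block F is
defined as 0 when the block adds nothing and infinite otherwise.

The descriptive factorial ANOVAs (trait and fitness differences across
population, morph, pollination; one-way pollinator-morphology comparisons)
use the same machinery on log10-transformed responses. Traits are strictly
positive so the default offset is 0; fitness can be 0 (fruitless plants), so
log-transformed fitness analyses require an explicit positive offset (+1 is
the conventional choice) and refuse to proceed otherwise.

## Bootstrap confidence intervals for PL

Individuals are resampled with replacement independently within each
treatment arm (the plant is the unit of fitness); PL is recomputed per
iterate (default 1000) and the 95% interval is the 2.5th/97.5th percentile
of the bootstrap distribution. Percentile is the default because it is the
simplest reproducible choice; BCa (jackknife acceleration over both arms) is
available via `method="bca"` and the method is recorded in every output.
Iterates whose resampled HP mean is zero leave PL undefined; they are
redrawn and counted. All resampling uses a named, seeded `numpy` generator;
per-group streams are spawned from the master seed so results are
reproducible and group-independent.

## Synthetic cohort generator

The generator emulates the study conditions: 16 cells (4 populations x 2
morphs x 2 treatments) with the published per-cell sample sizes (78–100),
trait means and SDs, hand-pollination mean fitness, and pollen limitation
(derived per group as 1 − W̄_C/W̄_HP from the published fitness means, never
stored as a separate constant).

* **Traits**: multivariate normal per cell; default correlations 0.2 (tube
  length–width) and 0.3 (height–flower number), zero elsewhere — weak enough
  to keep every linear-term VIF below 1.7. Draws are rounded to measurement
  precision (0.1 day, 0.1 cm, 0.01 mm; flower number to a positive integer)
  and clipped positive.
* **Fitness**: W = μ_W (1 + Σ β_i z_i) G, where z are the *realized*
  within-cell standardized scores, μ_W is the HP mean fitness (scaled by
  1 − PL in C cells), and G is gamma-distributed with mean 1 and coefficient
  of variation `fitness_noise_cv` (default 0.5, chosen to approximate the
  published fitness SD/mean ratios of ~0.5–0.85). β is defined on the same
  standardized scale the estimator reports, and the conditional mean is
  linear, so OLS recovers β without bias and without unit bookkeeping.
  Multiplicative gamma noise keeps seed counts non-negative and right-skewed,
  as real seed-set data are; the max(0,·) guard only engages when
  1 + Σβ_i z_i itself goes negative. Configuration validation caps the
  probability of that event at 1% per draw; under the default scenario the
  worst cell is at ~0.2% and the realized cohort-wide clip rate (logged per
  run) is ~0.02%.
* **Gradient scenario**: β_C encodes the study's findings — positive
  flower-number gradients everywhere (+0.20), positive tube-width gradients
  (+0.15 to +0.23), negative tube-length gradients only in L-morph plants of
  the syrphid-fly (BGTC) populations (−0.123, −0.167), a positive onset
  gradient in S-morph BGTC2 (+0.222) — and β_HP = β_C − Δβ with the Δβ
  pattern likewise confined to where the study reported it (tube-length
  contrasts −0.108/−0.25 in L-morph BGTC cells, tube-width contrasts
  +0.11 to +0.15 in every population, flower-number contrasts of mixed sign).
  Where only a subset of contrasts was printed, the remaining defaults were
  chosen once inside the reported ranges.
* **Reproductive bookkeeping**: fruit counts are binomial over flower number
  with a per-cell fruit-set fraction derived from the published fruit and
  flower means (clipped to ≥1 when seeds were produced), and seeds-per-fruit
  is W/fruits, so fruits x seeds-per-fruit reconstructs fitness exactly.
  These two columns are bookkeeping for schema completeness; the analysis
  uses total fitness.

What the generator does **not** emulate: real trait distributions are not
exactly normal (flower counts are overdispersed integers), fitness zeros
arise from herbivory and abortion rather than from the smooth tail of a
gamma, trait–fitness relationships may be nonlinear, and spatial/temporal
autocorrelation within populations is absent. Passing recovery tests
therefore demonstrates correctness of the estimation machinery under the
model's own assumptions, not robustness to real-data violations of them.

## Numerical and design choices

* Sample (n−1) SD for standardization; relative fitness from untransformed
  fitness; log10 transforms confined to the descriptive ANOVAs.
* Treatment coding throughout, reference level = first declared level
  (population: first appearance in the file; morph: L; pollination: HP, so
  pollination-interaction coefficients read directly as C − HP).
* Rank deficiency raises a named error identifying the aliased column;
  fits require n > p.
* Degenerate inputs are errors, not silences: zero-variance traits,
  zero-mean-fitness strata, missing treatment arms, and empty tables all
  raise with the offending group or column named. Rows with missing values
  are dropped on read with a logged count (field attrition is real but
  undescribed; imputation is deliberately not offered).
* Determinism: every stochastic stage takes an explicit seed; CLI artifacts
  record the seed and a configuration hash, and identical inputs + seeds
  produce byte-identical files (study tables round-trip CSV at full float
  precision).
* Problem sizes in the validation suite were chosen to make each check
  statistically meaningful at interactive runtimes: parameter recovery uses
  n = 2000 per cell over 50 seeds, null calibration 500 replicates at n = 60
  per cell, bootstrap coverage 500 replicates at field-scale n with 1000
  resamples each.

## Known limitations

* Selection is estimated through female fitness only; male-function
  selection requires paternity data the design does not collect.
* No nonlinear (quadratic) selection surfaces and no selection differentials;
  the correlational-term fit exists primarily to demonstrate the VIF
  screening outcome.
* No mixed-effects or spatial error structure; strata are treated as
  independent samples.
* The bootstrap interval type behind published CIs of this kind is often
  unstated; percentile and BCa can differ by a few hundredths at these
  sample sizes.
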