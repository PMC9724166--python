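# Methods

This note records the statistical model, the defaults and the design
choices behind `beachcast`, and what the synthetic-data tests do and do
not establish about real beach data.

## Generative model behind the analysis

Every stage assumes a site-season table of sampling events: environmental
covariates plus microbial indicator concentrations with left-censoring
flags. The working model for each indicator is sparse and linear on the
log10 scale,

    y_i = β0 + Σ_j β_j z_ij + ε_i,     ε_i ~ N(0, σ²),

where z_ij are standardized covariates, most β_j are zero, and the
observed concentration is the back-transform of y_i censored at the
indicator's detection limit or LLQ. Events are treated as exchangeable:
no within-season autocorrelation is modeled anywhere in the pipeline, and
the generator deliberately exposes no AR structure since none is assumed
downstream.

## Preprocessing

* **Response transforms.** Cultured and qPCR concentrations: log10(C).
  Coliphage: log10(C+1), because plaque counts fall below 1 PFU/L and the
  offset prevents negative logs. Censored values enter as ½·limit on the
  linear scale before transforming. A `substitute_fraction` switch allows
  substituting the full limit instead (some workbooks read the rule that
  way for qPCR responses); the default is ½ in all families.
* **Wind decomposition.** Wind arrives as meteorological "direction from";
  it is flipped to "toward" and projected on the shore-normal frame:
  wind_O = s·cos(θ), wind_A = s·sin(θ), θ = (direction+180°) − shore-normal
  azimuth (water→land). The components always satisfy
  wind_A² + wind_O² = s². The sign convention (onshore positive) is fixed
  here because published analyses rarely state one, and signs must be
  reproducible for coefficient heatmaps to be interpretable.
* **Standardization** subtracts the column mean and divides by the sample
  sd (ddof = 1), per site-season dataset — models are site-specific, so
  pooling scales across sites would leak cross-site location information.
* **Collinearity filter.** For each covariate pair with |r| ≥ 0.8 exactly
  one member is dropped. Members of a configured exclusion list (UV254,
  48 h rainfall in the shipped defaults) are dropped preferentially;
  otherwise the member with the larger total absolute correlation to all
  other covariates goes. Pairs are resolved strongest first, so three
  mutually collinear columns keep exactly one survivor. The filter acts on
  empirical correlations, so at n ≈ 65 a pair whose population r sits just
  below 0.8 can still be flagged — that is faithful behavior, not a bug.

## LARS-lasso and minimum-Cp selection

The solver is a from-scratch least-angle regression with the lasso
modification. The response is centered (the intercept is the response
mean); covariates must arrive standardized. Each step moves along the
equiangular direction of the active set until an inactive covariate's
absolute correlation with the residual ties the active correlations
(entry) or an active coefficient hits zero (a lasso drop, which is itself
a path step). When n > p and the design has full rank, the last step is
the OLS solution.

Numerical choices:

* Entry ties break by column order (logged). An entrant whose Gram matrix
  would be numerically singular (condition number > 1e10) is skipped with
  a logged warning.
* Step count is capped at min(n−1, 8p); the active set at min(p, n−1).
* σ̂² for Cp is the classical full-OLS estimate RSS_full/(n−p−1); for
  saturated or rank-deficient designs it falls back to the last path
  step's RSS over its residual degrees of freedom.
* Cp_k = RSS_k/σ̂² − n + 2·df_k with df_k = |active|+1. If σ̂² is
  numerically zero (an exactly-fitting model), Cp degenerates to 2df_k − n
  for exact-fit steps and +∞ otherwise, so selection returns the sparsest
  exact fit — this is what makes noise-free cross-validation checks exact.
* Ties in min-Cp break toward the earlier (sparser) step.

A structural property of minimum-Cp selection **along the lasso path**
deserves note: at the breakpoint where the last true covariate has just
entered, all active coefficients are still shrunk by the next entry
threshold, which inflates that step's RSS by roughly 2k·ln(p) units of σ²
(k = active size). Later steps relieve the shrinkage, so the Cp minimum
tends to sit beyond the true support even under very strong signal. The
selected active set therefore usually *contains* the true support rather
than equalling it, and on pure noise the null model is the modal but not
dominant outcome. This behavior is shared bit-for-bit by independent
path-based selectors (scikit-learn's `LassoLarsIC` scores identically on
the same replicates) and is visible in published applications of this
selector, where single models range from all-zero to all-nonzero
coefficient vectors.

## Cross-validated scoring

Data are split into k = 10 folds (random permutation cut into nearly equal
blocks; no stratification). Each fold is predicted by a sub-model trained
on the other nine, *including re-standardization of the training
covariates* — the withheld fold contributes nothing to the scales, which
is the defensible choice even though published descriptions are usually
silent on it. Columns constant within a training fold are dropped from
that sub-model with a warning.

SRMSEP divides the out-of-fold RMSE by C̄, the mean of the full observed
(substituted) log10 response of the model's dataset — the formula
references the modeled indicator's average concentration, not the withheld
folds. R²PRED is the squared Pearson correlation between predictions and
observations; degenerate constant predictions score 0 with a warning.
Board standardization divides each metric by its maximum over whatever
model set is supplied, so standardized values are reproducible only with
an explicit model set; Overall Performance = std R²PRED + (1 − std SRMSEP)
∈ [0, 2].

## Censored correlations

Each repetition replaces every below-limit value with an independent
Uniform(0, limit) draw on the linear concentration scale, then applies the
same log transform as the indicator's response (including the +1 offset
for coliphage) before computing Pearson r; 100 repetitions by default. The
t-test is applied to the averaged r with n−2 degrees of freedom,
two-sided. An `impute_scale="log"` variant draws uniformly on the log10
scale instead. Worth knowing: the log10 of a Uniform(0, L) draw has a
heavy left tail, so with 20% censoring at n ≈ 65 the imputation spread of
r is on the order of 0.05 — substantially larger than would arise if
correlations were computed on the linear scale, where below-limit values
are numerically negligible.

## Covariate influence

One minimum-Cp model per site/indicator on all data; only coefficients are
used. Scores per covariate: summed |coefficients| across models,
proportion of models with a non-zero coefficient, and their sum (Total
Score). The occurrence denominator counts only models where the covariate
was available, so a single-site covariate (e.g. river discharge) is scored
over that site's models. Groups (rainfall lags; the two wind components)
sum member magnitudes and count a model once if any member is non-zero —
union semantics, because a proportion cannot exceed 1. Heatmap matrices
keep signed coefficients in alphabetical covariate order, with an NA mask
for covariates unavailable at a site, never conflated with an exact zero.

## qPCR quantification and QC

Standard curves are weighted linear regressions of Ct on log10 copies per
reaction over composited multi-run dilution series. The default weight
scheme weights each level by its replicate count, which on per-well data
equals the OLS fit to individual points; equal-per-level and explicit
weights are available. Amplification efficiency is 10^(−1/slope) − 1 and
the ΔΔCt amplification base is efficiency + 1 — taken from the assay's own
curve rather than assumed to be 2, which keeps the ΔΔCt and direct-curve
quantification routes mutually consistent (their ratio is exactly 1 on
noiseless data). CSE→CCE conversion is a configurable factor (default 1).

The sample-level LLQ derives from the lowest quantifiable standard and the
extract fraction analyzed per reaction: 6 copies/reaction ÷ (1/120) = 720
copies/sample (100 mL).

QC gates, one pass/fail row each with the observed statistic: (1) ANCOVA
parallelism of per-run standard curves via nested F-tests (common-vs-
separate slopes, then intercepts), acceptance p > 0.05, with p = 1 by
convention when the incremental sum of squares is zero; (2) calibrator
target and Sketa22 Ct within ±3 reference SDs; (3) test-sample Sketa22 Ct
within 3 units of the calibrator Sketa22 mean; (4) test-sample IAC Ct
within 1.5 units of the negative-control IAC mean; (5) negative-control
ΔΔCt estimate (computed *before* any Sketa22 adjustment) below the LLQ;
(6) duplicate target-Ct standard deviation within 1.414. Undetected Ct is
a sentinel distinct from any number ("ND" in CSV); the value 40 is
substituted only inside averages. A gate whose required controls are
absent is reported "not evaluable", never silently passed; the overall
verdict is the conjunction of evaluable gates.

## Synthetic-data generator

The generator defines the study conditions for all tests:

* **Covariates** (19 defaults): the routine water and beach-site suite with
  magnitudes typical of a mid-summer Great Lakes beach — gaussian
  (temperatures, DO, conductivity, pH, humidity), lognormal (turbidity,
  DOC, UV254, wind speed, wave height, rainfall lags, PAR), negative-
  binomial counts (humans, birds, dogs) and a wrapped-normal wind
  direction. Dependence comes from a Gaussian copula; for gaussian and
  lognormal marginals the latent correlation is inverted in closed form so
  the *target Pearson r* is matched, not attenuated (counts and directions
  use the latent r directly, which is approximate). Shipped collinear
  targets: UV254–DOC 0.81, rain 24–48 h 0.84, rain 48–72 h 0.89, plus an
  implied rain 24–72 h 0.75 required for a positive semi-definite target.
* **Indicators** (7 defaults): sparse signals dominated by rainfall, bird
  abundance and wave height; intercepts and noise chosen so log10 spreads
  sit near 0.4–0.6 and censoring ranges from none (somatic coliphage,
  *Bacteroidales*) to ~25% (F+ coliphage, deliberately the weak-signal
  high-censoring regime). Censoring is applied to the noisy back-
  transformed measurement — detection limits act on the measurement, not
  the latent mean.
* **qPCR plates**: six standard levels from 6 to 6×10⁵ copies/reaction in
  triplicate across two instrument runs, triplicate whole-cell calibrators
  and filter-blank negatives, duplicated test samples, with target, IAC
  and Sketa22 channels; `inject_failures` perturbs the plate so a named QC
  gate — and only it — trips.
* **Seeding**: one config seed, split into documented child streams
  (`SeedSequence([seed, k])`), so covariates, response noise and plate
  noise re-draw independently but reproducibly; identical seeds give
  bit-identical outputs.

What the generator does *not* emulate: within-season autocorrelation and
storm clustering, spatial structure within a beach, zero-inflation of
rainfall, reporting artifacts (ties at method quantification steps), or
inter-assay correlation of qPCR noise. Passing tests therefore establish
correctness of the statistical machinery under the stated model, not
forecast skill at any real beach.

## Problem sizes

Defaults keep every stage light: seasons of 65 events (the per-site scale
of a five-day-per-week beach season), 10 folds, 100 imputation
repetitions, Monte-Carlo suites of 20–100 replicates at n ≤ 200 and
p ≤ 10. The full analysis chain runs in seconds on one core.

## Known limitations

* Only row-wise deletion for missing covariates; no imputation.
* No cross-validated λ selection, elastic net or coefficient inference —
  selection is by minimum Cp only, with the path-selection bias described
  above.
* The coliphage linear detection limit is a configuration parameter (the
  log-scale value a published table prints for it is not derivable from
  any stated linear limit under the log10(C+1) transform).
* Correlation p-values carry no multiple-testing correction across pairs.
* The copula matches Pearson targets exactly only for gaussian/lognormal
  pairs; count and circular marginals attenuate slightly.
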