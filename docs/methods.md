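# Methods

This note documents the statistical models implemented in `thermofda`, the
numerical choices behind them, what the synthetic cohort generator does and
does not emulate, and the known limitations.

## Curve representation and smoothing

Thermograms arrive as long-format tables of excess specific heat capacity
at discrete temperatures.  Preprocessing truncates each subject's record to
a working range (default 45–90 °C), linearly interpolates onto a closed
uniform grid (default 0.1 °C, giving 451 points) and refuses to
extrapolate: a subject whose observed range does not cover the window is an
error, not a silent fill.  Linear interpolation is used because it is
monotone and overshoot-free, which matters on the steep flanks of
denaturation peaks.  Temperatures are matched with a 1 µ°C tolerance.

Curves are expanded in a cubic (order-4) B-spline basis with equally spaced
interior knots, fit by ordinary least squares on the grid.  Cubic splines
are the de-facto standard for smooth univariate functional data on a
uniform grid; no knot-placement heuristic is warranted when the grid itself
is uniform.  Two regimes are used:

* **Saturated basis** (K = number of grid points): interpolates the data
  exactly.  This is the representation upstream of FPCA, where no smoothing
  bias is wanted.
* **GCV-selected basis** for coefficient functions in the functional
  regression.  The cohort criterion is `GCV(K) = Σ_i T·SSE_i/(T−K)²`, the
  per-curve generalized cross-validation summed over subjects (the
  unpenalized least-squares hat matrix has trace exactly K).  The saturated
  candidate K = T is reported as +∞ (its GCV is 0/0) so selection never
  degenerates to interpolation.  Candidates default to coarse steps plus
  the saturated value.

No roughness penalty is applied by default anywhere: dimension selection by
GCV plays that role.  Derivative ("velocity") curves are the analytic
derivatives of the spline expansion, optionally re-projected onto the same
basis to obtain a coefficient matrix of their own; on a saturated basis the
re-projection is exact to solver precision.

## Functional-response regression

The model is `y_i(t) = β₀(t) + Σ_j x_ij β_j(t) + ε_i(t)` with categorical
predictors.  Two codings are provided:

* **Reduced** (two-group): intercept plus redundant ±1 case and control
  columns.  The redundancy is resolved by the standard sum-to-zero
  constraint `β_case(t) + β_control(t) = 0`, enforced pointwise through the
  KKT system of the constrained least-squares problem, which makes β₀ the
  grand-mean curve and the group perturbations mirror images.  Note the
  algebra of this coding: a case's predictor is β₀ + β_case − β_control, so
  the case-minus-control difference curve is 4·β_case.
* **Full**: treatment (baseline-contrast) coding for status, sex, race and
  four year-of-birth categories — intercept plus six predictor functions,
  i.e. seven coefficient functions in total.

Estimation is pointwise least squares on the grid followed by projection of
each β_j onto the coefficient basis; for a common basis this is equivalent
to solving for the basis coefficients directly and is trivially checkable
against group-mean oracles.  The response curves are smoothed onto the same
basis first, so fitted-plus-residual reconstructs the smoothed response
exactly and residual functions are orthogonal to the design span to solver
precision.  Residuals are reported against the smoothed curves: the
smoothing step is part of the pipeline's model, and defining residuals
against raw curves would mix basis-approximation error into the regression
diagnostics.

## Permutation t- and F-tests

Pointwise statistics are computed on the smoothed curves evaluated on the
working grid:

* t: `|x̄₁(t) − x̄₀(t)| / sqrt(s₁²(t)/n₁ + s₀²(t)/n₀)` — Welch (unpooled)
  form, robust to group-variance imbalance.
* F: `Var_i(ŷ_i(t)) / mean_i[(y_i(t) − ŷ_i(t))²]` — the variance-explained
  ratio.  **This is not the classical ANOVA mean-square ratio**; values
  well below 1 are routine and entirely compatible with overwhelming
  significance (e.g. an observed max of 0.35 against a permutation critical
  value of 0.06).  The convention is the one long established for
  functional permutation F-tests, and the permutation calibration makes
  the scale irrelevant to the decision.

Null distributions come from relabeling curves (t) or permuting response
rows against the fixed design (F), default 200 permutations.  The
pointwise critical value is the per-temperature (1−α) quantile of permuted
statistics; the maxwise critical value is the (1−α) quantile of the
permutation maxima, and the overall null is rejected iff the observed
maximum exceeds it.  Ties in the argmax location break toward the lowest
temperature.  Denominators at float-roundoff level (numerically identical
groups, perfect fits) are treated as exact zeros rather than producing
noise-ratio statistics.

## FPCA

The covariance-operator eigenproblem is discretized with trapezoidal
quadrature weights W on the grid: eigendecompose the symmetric matrix
`W^{1/2} C W^{1/2}` (C the 1/(n−1) sample covariance of the curves) and
back-transform eigenvectors by `W^{-1/2}`.  This yields eigenfunctions with
quadrature norm 1, scores whose sample variance equals the eigenvalue, and
exact conservation `Σ_j μ_j = ∫ v(t,t) dt`.  On a fine uniform grid this
route is numerically equivalent to the basis-coefficient route and far
easier to verify against a dense-matrix oracle; the test suite does exactly
that on random small instances at 1e-8.

Signs are fixed deterministically — each eigenfunction is oriented so its
integral is positive, tie-broken by its value at the lowest temperature —
so repeated runs and split replicates are comparable.  Harmonic count J is
the smallest number of components whose cumulative variance proportion
reaches a threshold (default 99 %), capped by a configurable maximum (the
evaluation default is 15) so that near-degenerate tail components never
enter the classifier.  Variation curves are `mean ± √μ_j·ξ_j`.  New curves
(held-out test subjects) are scored against the training mean and
harmonics by the same quadrature inner product.

## Score-logistic classification

Status is regressed on FPC scores (thermogram γ, optionally velocity τ) by
maximum-likelihood logistic regression (statsmodels GLM, binomial family).
Inference is Wald: SEs from the observed information, odds ratios exp(β)
with 95 % CI exp(β ± 1.96·SE), matching the conventional coefficient-table
layout.  Perfect separation is detected (flat-likelihood fits or runaway
coefficients) and *flagged*, not raised — a separable training split is a
legitimate outcome on strongly separated data, and the evaluation loop must
carry on.  Classification uses a fixed probability cutoff of 0.5, with
probability exactly 0.5 classified control (the case rule is strictly
"greater than").

Composite representative curves take the PCs with Wald p < α, push each
significant score one SD in the direction of its coefficient sign
(`mean + Σ sign(β_j)·√μ_j·ξ_j` and its mirror), and report the fitted
probabilities of those two synthetic score vectors.  The sign pattern is
derived from the fitted coefficients rather than hard-coded, so it adapts
to the data at hand.

## Repeated-split evaluation

Each replicate draws a stratified random split without replacement:
default training counts are two thirds of each group (a 592-subject cohort
with 298/294 groups uses the historical fixed 200/200).  By default
(`fpca_mode="per_split"`) the FPCA mean, harmonics and the 99 %-rule J are
re-estimated on the training curves only and the test subjects are scored
by projection — the statistically clean protocol, since estimating
harmonics on all data before splitting leaks information.  A `global` mode
(FPCA once on everything) is also provided for comparison with workflows
that fit FPCA before splitting.  Metrics are per-split accuracy,
sensitivity and specificity (case = positive), averaged over splits, with
the normal-approximation interval `mean ± 1.96·sd/√R` (sample SD).  The
RA/OA metric is the fraction of arthritis-flagged, lupus-negative subjects
in each test set classified control; splits without such subjects
contribute nothing.  Sensitivity/specificity are averaged per-split (not
pooled over subjects).  One master seed drives a `SeedSequence` spawn per
split, and `compare_models` reuses the identical split sequence across the
thermogram / velocity / combined rows so model differences are
split-for-split.

## Synthetic cohort generator

The generator emulates the statistical structure of a matched case/control
DSC study: ~300 + ~300 subjects on the 45–90 °C / 0.1 °C grid, a bimodal
control template (Gaussian peaks at 63 °C and 70.5 °C, widths 2.2/2.8 °C,
amplitudes 0.60/0.52 in arbitrary normalized heat-capacity units), and a
case contrast that transfers amplitude from the first-peak region
(−0.10·N(63.5, 2.2)) into the 72–85 °C shoulder (+0.08·N(76, 3.5)) with a
0.4 °C rightward shift — reproducing "bimodal controls, more unimodal
cases" with the group difference concentrated in [60, 69] ∪ [72, 85] °C.

Three variance components make the cohort realistically hard to classify:

* **disease-expression heterogeneity** — each case scales the contrast by
  `effect_size · N(1, effect_het)` (default heterogeneity 0.7), so mild
  cases overlap the control cloud; a homogeneous effect of this magnitude
  would make the groups perfectly separable, which no real autoimmune
  cohort is;
* **subject-level peak variation** — amplitude multipliers N(1, 0.2) and
  center jitter (SD 0.4 °C) per peak;
* **smooth residual noise** — Gaussian coefficients (SD 0.02) on a coarse
  B-spline basis with 3 °C knot spacing.  Smoothness matters: white grid
  noise would dominate saturated-basis FPCA and explode under
  differentiation, neither of which instrument-filtered DSC data do.

`effect_size = 0` makes the two group distributions exactly identical
(controls consume the same random-number stream), which is what the
type-I-error and null-accuracy checks rely on.  RA/OA-flagged controls are
drawn from the control distribution (they are non-lupus controls); a
perturbation knob exists but defaults to 0.  Covariates (sex 90 % F, race
50/50, four birth-year categories) are drawn independently of status,
mirroring a matched design in which covariates carry no disease signal.
Amplitudes are arbitrary: real thermogram units depend on the
normalization convention and are not claimed.

What the generator does **not** emulate: instrument baselines and their
subtraction, concentration normalization error, aggregation artifacts
above 90 °C, covariate–disease confounding, and any specific biochemical
mechanism.  Passing tests therefore demonstrate the correctness and
calibration of the statistical machinery under the assumed curve model,
not clinical performance on real plasma.

When counting "peaks" of generated mean curves, local maxima are filtered
by a small prominence floor (1 % of peak amplitude): averaging smooth noise
over hundreds of subjects leaves O(10⁻³) ripples in the flat tails that are
not denaturation peaks.

## Problem sizes and determinism

The test suite and the acceptance script generate everything in-process.
Representative sizes, chosen to exercise each property at comfortable
statistical resolution: dense-oracle FPCA instances at n ≤ 10, T ≤ 12;
type-I calibration over 200 null cohorts of 30+30 subjects on a 101-point
grid with 100 permutations; effect-size response at 3 effect sizes × 20
seeds × 4 splits; the acceptance pipeline itself on the full 600-subject,
451-point cohort with 200 permutations and 1000 evaluation splits.  Every
stochastic quantity flows from a single seed through `SeedSequence`
substreams; derived seeds stay below 2³¹.

## Known limitations

* The F statistic's variance-ratio convention means its magnitude is not
  comparable to classical ANOVA F tables; only the permutation calibration
  gives it inferential meaning.
* Pointwise-then-project estimation of coefficient functions is exact only
  because the response is pre-smoothed onto the same basis; with a
  different coefficient basis the equivalence is approximate.
* The evaluation's per-split FPCA re-selects J by the variance rule, so
  different splits may use different score dimensions; this is intended
  (it is part of the pipeline being evaluated) but means coefficient
  estimates are not pooled across splits.
* Wald inference near separation is unstable; the separation flag should
  be checked before interpreting coefficient tables on small cohorts.
* No registration/warping: curves are compared at face temperature value,
  as is standard for buffer-controlled DSC.
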