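# Methods

`sbamix` models plot-level stand basal area (SBA, m² ha⁻¹) for a
two-species broad-leaved mixed forest (*Populus davidiana* × *Betula
platyphylla*) and for the whole stand, under the constraint that predicted
species values sum exactly to the predicted stand total. This note
documents the models, the estimators, the synthetic-data generator and the
numerical choices, including the places where the design was genuinely
open.

## Model forms

All predictors are nonlinear in three stand covariates: site index `SI`
(dominant height, m), breast-height age `ADBH` (years) and Reineke stand
density index `SDI = N·(D0/Dg)^−1.605` with reference diameter `D0 = 20` cm
(`N` stems ha⁻¹, `Dg` quadratic mean DBH, cm). Three age-only base growth
functions are provided (Korf `b0·exp(−b1·t^−b2)`, Schumacher
`b0·exp(−b1/t)`, Richards `b0·(1−exp(−b1·t))^b2`; 3, 2 and 3 parameters)
plus six extended forms M1–M6 (see `sbamix.forms`). M2/M4/M6 use
`SDI/1000`; the unscaled SDI is always stored and the division happens
inside the predictor.

Two open choices were resolved as follows:

* **M5/M6 grouping.** The Richards-type extended form is read as
  `b0·SI^b1·[1 − exp(−b2·S^b3·ADBH)]^b4` (rate inside the exponential,
  shape exponent outside), consistent with the base Richards skeleton.
  Every alternative grouping of the flattened expression produces
  nonsensical magnitudes (10⁻²⁷ or several times the observed stand
  totals) when evaluated with the published coefficient sets at the mean
  covariates, while this reading lands on the observed species means.
* **Species vs stand SDI.** Species-level equations default to the
  species-partial SDI (the published data summary reports species-level
  SDI columns whose means approximately sum to the stand value); a column
  map lets users supply whole-stand SDI instead.

Predictions are evaluated in log space. A proposal whose log prediction
exceeds 700 in magnitude, or whose Richards bracket is negative, is
*declined* (an `EvaluationError`, or NaN on the fitting path) rather than
clamped, so optimizers feel a penalty instead of a silent plateau.
`b0 = 0` returns 0 as the continuous limit.

## Equation-wise NLS

`fit_nls` minimises the residual sum of squares with SciPy's trust-region
least-squares solver. Positivity-constrained parameters — the leading
scale everywhere except the log-linear M3/M4 (whose leading coefficient is
already a log-scale quantity and may be negative), plus the Richards rate
(`b1` base / `b2` extended), which must be positive for the bracket to be
defined — are log-reparameterised; everything else is unbounded, because
published M3/M4 estimates include negative values.

Multi-start initialisation: start centres are the published coefficient
sets matching the form plus a data-driven centre (exact log-scale OLS for
the log-linear forms M1–M4 and the base forms; fixed heuristics for
M5/M6), expanded with log-uniform perturbations (±1 order of magnitude on
the scale, ±50% elsewhere) up to `n_starts`. Convergence uses a relative
SSE tolerance of 1e−10 with at most 500 iterations per start. The lowest
final SSE wins; optima tied within a relative 1e−9 keep the earliest
start. The tie rule matters on weakly identified ridges (below), where
strict minimisation would otherwise drift to arbitrary ridge coordinates.

Standard errors are the usual asymptotic `s²(JᵀJ)⁻¹` with
`s² = SSE/(n−p)`. The Jacobian is differenced in the working
(log-reparameterised) space and mapped back by the delta method — this
keeps every evaluation inside the parameter domain and stays
well-conditioned when coefficients span orders of magnitude. A
rank-deficient information matrix falls back to the pseudo-inverse and is
flagged; an (essentially) zero residual variance reports zero SEs with a
flag rather than NaN.

`rank_models` orders candidate forms by descending adjusted R², ties by
ascending RMSE then parameter count, non-converged fits last. In-sample
and cross-validated metrics are reported separately and labelled, since
either could be meant by a model-selection table.

## The AP additive system

The proportional-adjustment system models the whole stand directly,
`SBA_t = f_t(b, X_t) + ε_t`, and the species as model-based shares,
`SBA_s = f_s/(f_P + f_B) · SBA_t + ε_s`. Because the total equation
contains only total-model parameters and the share equations only species
parameters, estimation separates: stage 1 fits `f_t` by NLS; stage 2
estimates both species surfaces jointly by minimising the stacked SSE of
the two share equations (the weights couple the species, so they cannot be
fitted one at a time). The observed total stands on the right-hand side
during estimation — that is the equation as written — while prediction
substitutes the fitted total, so predicted components always sum exactly
to the predicted total. A one-stage simultaneous fit of all three
equations is available behind `simultaneous=True` for comparison.

Two structural facts shape the uncertainty reporting:

* With additive data (`sba_p + sba_b = sba_t`, enforced at ingest to
  1e−6), the two share-equation residual vectors are exact negatives, so
  the stacked system carries the information of n, not 2n, observations;
  `s²` and the information matrix are scaled accordingly.
* Multiplying both species surfaces by a common positive constant leaves
  every share weight — and hence the entire fit — unchanged. The two
  leading scales are therefore identified only up to a common factor. No
  normalisation is imposed (published practice reports both scales
  freely); the covariance of the flat direction is handled by
  pseudo-inversion and flagged, and the fit reports the identified
  contrast `b0_P/b0_B` with a delta-method SE.

Stage 2 starts from equation-wise NLS fits of each species surface (plus
published sets), the standard system-fit initialisation.

## The NSUR additive system

Nonlinear seemingly unrelated regression estimates the two species
equations jointly under a cross-equation error covariance Σ, with the
stand total obtained structurally as the component sum. In field data the
observed total *is* the arithmetic sum of the components, so a
three-equation system would have an exactly singular 3×3 covariance; the
estimator therefore uses the two species equations with a 2×2 Σ — the
standard resolution for additive component–total systems. An
`include_total=True` option adds the third equation with a
ridge-stabilised covariance for totals measured independently.

Estimation is iterated feasible GLS: equation-wise NLS starts; then
`Σ̂ = RᵀR/n` from the species residual matrix (divisor n, not n−p — simpler
and consistent); then joint minimisation of `Σᵢ rᵢᵀ Σ̂⁻¹ rᵢ` with residual
pairs whitened by the Cholesky factor of Σ̂; then re-estimation of Σ̂, until
the maximum relative parameter change drops below 1e−8 or 50 outer
iterations. A singular Σ̂ raises an error suggesting the ridge option.
Standard errors come from the inverse GLS information (whitened Jacobian,
no extra variance factor), again via the working-space/delta-method route.
With independent errors NSUR coincides asymptotically with equation-wise
NLS; with correlated errors the per-parameter SE ratio (`efficiency_gain`)
is typically below 1.

## Goodness of fit, comparison, cross-validation

`compute_metrics` implements MAE, MPE = Σ|e|/Σy × 100, RMSE, R² and
adjusted R² literally. MPE is computed on the percent scale; the published
comparison table for this system prints it as a proportion, so the report
also exposes `mpe_proportion`. Percent-change comparisons between methods
are invariant to that choice. Undefined cases (zero total for MPE, zero
response variance for R²) yield NaN with a flag, not an exception.
`percent_change` reports a decrease as `(before − after)/before × 100` and
an increase as `(after − before)/before × 100`, both as positive
magnitudes with the direction attached.

Cross-validation shuffles plots with a mandatory recorded seed and splits
the permutation into k near-equal contiguous blocks (k = 10 by default; 58
plots give eight folds of 6 and two of 5), without stratification. Each
fold is predicted by a model refitted to its complement; pooled metrics
are computed on the concatenated out-of-fold predictions, using the
refitted equation's own parameter count. A failed fold is recorded and
skipped, not fatal.

## Synthetic plot generator

The generator emulates the study stands: 58 plots of 30 m × 30 m by
default. Covariates (SI, ADBH, SDI, Dg) are drawn independently per
stratum from truncated normals parameterised by the published per-stratum
mean/SD/min/max (no cross-covariate correlations are published; a
correlation hook exists for sensitivity work). Stem counts are back-derived
from SDI and Dg through the Reineke identity, so ingest-time derivation is
exercisable on synthetic files.

Two response modes:

* **component** (default): species SBAs are their model surfaces (defaults:
  the published NSUR sets — Richards-type M6 for *P. davidiana*, Korf-type
  M1 for *B. platyphylla*) plus a correlated Gaussian error pair; the
  total is the exact component sum. Default error scales σ_P = 0.63,
  σ_B = 0.41 are the published species RMSEs; the cross-species error
  correlation is not published and ρ = 0.5 is a documented stand-in.
* **share**: the total follows the published whole-stand surface plus
  noise (σ_t = 1.776, its published RMSE), and species values are share
  splits of the observed total with share noise (σ_P = 0.709); the
  complement construction keeps additivity exact. This is the
  data-generating scheme under which the AP estimator is correctly
  specified.

Negative basal areas are rejected and redrawn (up to 100 attempts per
plot, then a configuration error) rather than truncated, to avoid biasing
the error distribution near zero. Generation is bit-identical for a given
(config, seed).

What passing tests on these data do *not* show about real stands: real
covariates are cross-correlated (site quality, age and density are not
independent), species composition varies systematically across plots, and
real residuals need not be Gaussian or homoscedastic. The generator
validates the estimators, not the ecology.

## A known identifiability limit

At the published coefficient scales, the Richards-type M6 surface operates
with its saturation bracket deep in the linear regime (inner argument
≈ 3×10⁻⁵ at the mean covariates). The model then degenerates towards a
power law in which only the product `b0·b2^b4` — not the scale `b0` and
rate `b2` separately — is identified. Consequences, visible in the
parameter-recovery experiments (`sbamix.experiments`):

* the profile likelihood over `b2` is nearly flat below ≈ 0.03, so point
  estimates land on an arbitrary ridge coordinate;
* per-coefficient Wald intervals for the scale pair under-cover badly (the
  ridge is strongly curved, so no local quadratic — in raw or log space —
  describes it), a classic Wald-vs-profile-likelihood gap;
* the published SEs for these coefficients are themselves enormous
  relative to the estimates, corroborating the weak identification.

The experiments therefore report strict every-coefficient recovery rates
alongside rates restricted to the identified quantities (exponents, the
well-identified Korf-type equation, the AP scale ratio). The strict rates
for systems containing M6 are low by construction, and are reported as
measured rather than patched; the identified-subset rates are the
meaningful check of estimator correctness. For NSUR the identified subset
recovers at the nominal level. For AP the identified subset still dips
below nominal because its scale ratio involves `b0_P`, which rides the
same curved ridge; the exponents and the total-stand equation recover
cleanly.

## Problem sizes

Defaults chosen for the simulation studies: recovery experiments use 100
replicates at n = 400 plots (NSUR; σ_P = 0.6, σ_B = 0.4, ρ = 0.5) and
n = 300 plots (AP; σ = 0.5); the SE-coverage property of the
well-identified M1 equation uses 200 replicates at n = 500, σ = 0.4;
large-sample generator calibration uses n = 5000. These sizes give
Monte-Carlo standard errors of a few percentage points on the reported
rates.
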