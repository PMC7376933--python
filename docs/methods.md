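# Methods

## Response families

Six distributions are available for the flexion outcome, all
parameterised so that `mu` is the **median** (centile curves then read
directly off the parameters): normal NO(μ, σ) and gamma GA(μ, σ) with two
parameters; the t family TF(μ, σ, ν) and Box-Cox Cole–Green BCCG(μ, σ, ν)
with three; Box-Cox t BCT(μ, σ, ν, τ) and Box-Cox power-exponential
BCPE(μ, σ, ν, τ) with four. For GA the conventional shape/scale form
(shape `1/σ²`, so σ is the coefficient of variation) is rescaled so the
50th percentile sits at μ; deviances are invariant to that
reparameterisation.

The Box-Cox families transform `y` through
`z = ((y/μ)^ν − 1)/(νσ)` (logarithmic branch when `|ν| < 1e-7`, a
removable singularity) and model `z` as a standard normal, Student-t(τ),
or unit-variance power-exponential(τ) kernel, truncated to the region
compatible with `y > 0`. The truncation constant is evaluated in log
space; quantiles invert the truncation-adjusted CDF exactly, so density,
CDF and quantile function are mutually consistent to numerical precision.
A consequence worth knowing: the median equals μ only up to the
truncation mass `K(−1/(σ|ν|))` — about 1e-7 relative at the scales this
package fits (σ ≈ 0.1, |ν| ≤ 2) and at worst ~2e-4 for heavy-tailed
kernels, which is far below measurement resolution (goniometry is read
in whole degrees).

Sampling is inverse-CDF throughout, which makes draws exactly consistent
with the quantile function used to build charts — the property the
Monte-Carlo coverage calibration tests rely on.

## Smoothing and the time transform

Time enters as `x = t^p` with `p > 0`; `p ≈ 0.5` linearises the fast
early phase of recovery. Each parameter curve is a natural cubic
smoothing spline in `x` with knots at the distinct observed values,
fitted by penalized weighted least squares. Flexibility is specified as
**effective degrees of freedom** — the trace of the linear smoother
`S_λ = (W + λK)⁻¹W` — which is continuous in λ: edf 2 is the weighted
least-squares line (λ → ∞) and edf = n_distinct is interpolation
(λ → 0). Fractional "knots" such as 2.2 therefore mean edf = 2 + 2.2 for
that curve; the penalty achieving a requested edf is found by bisection
on log λ (tolerance 1e-3 on the trace). Duplicate x values are pooled
with summed weights. Prediction outside the observed range continues the
natural spline linearly; `SmoothFit.in_range` exposes where that
happens.

## Fitting

`fit_gamlss` maximises the penalized likelihood by RS-type backfitting:
cycle over parameters; for each, compute the score `u` and curvature `f`
of the log-likelihood with respect to that parameter's linear predictor
(central finite differences of the exact log-density, step
`1e-4·(1+|η|)`), form the working response `η + u/w` with weights
`w = max(f, floor)`, fit the weighted smooth (or weighted mean for a
constant term), and step-halve the update until the global deviance does
not increase. The deviance trace is therefore non-increasing by
construction. Convergence requires |Δ deviance| < 1e-7 on two
consecutive cycles (maximum 200); the tight default costs only a few
extra Newton-quality cycles and makes intercept-only fits agree with
closed-form maximum likelihood to ~1e-6. Non-convergence raises an
error carrying the deviance trace, or returns the best-so-far model
flagged unconverged when `strict=False` (the mode used inside
cross-validation and hyperparameter search, where an occasional slow
fold should degrade a score rather than abort a study).

Links: identity for μ (flexion is far from zero; positivity is enforced
by rejecting any update that leaves the support, which the step-halving
machinery handles naturally) and for the Box-Cox skewness ν; log for σ
and for the strictly positive shape parameters — including the TF
degrees of freedom, where an identity link would permit invalid values.
Log-link predictors are clamped to ±12. Initial values: μ from an
unweighted smooth (or median) of `y`; σ from a moment estimate of the
residual scale; ν = 1 (Box-Cox) or df = 10 (t kernels); τ = 10 (BCT) or
2 (BCPE).

Observations are treated as independent even though patients contribute
repeated measures — matching how such charts are built in practice. The
generator's `patient_effect_sd` knob exists precisely to study the
consequence: with within-patient correlation switched on,
observation-level cross-validation folds leak information and report
optimistic MSE relative to patient-level folds (a tested property), which
is why **cross-validation partitions patients, not observations**, by
default.

## Model selection

`SBC = deviance + df·log(n)` with the summed effective df (2 + extra per
smooth term, 1 per constant). Candidates are ranked by SBC; among those
within ΔSBC ≤ 5 of the best, ranking switches to centile-coverage error,
then cross-validated MSE, then fewer total df — encoding the practice of
preferring the simplest accurately-calibrated chart among statistical
near-ties. `optimize_hyperparameters` minimises SBC over (df_μ, df_σ,
power) with Nelder-Mead from jittered multistarts (df clipped to [0, 10],
power to (0.05, 1.5]); the initial point is always evaluated, so the
returned optimum can never be worse than the starting specification.
Scoring inside selection and search uses a relaxed convergence tolerance
(1e-4 to 1e-3) — deviances are O(10³), so this does not move rankings.

## Charts, coverage, validation

Charts evaluate the fitted centiles on integer days 2–120 (the
observation window) at levels {5, 10, 25, 50, 75, 90, 95}%; strict
monotonicity across levels is asserted at build time and never silently
repaired. Coverage counts observations **strictly below** a curve at the
observation's own day (model mode) or at linearly interpolated grid
values (chart mode, which excludes and counts out-of-grid records); exact
ties count as not-below — an arbitrary but fixed convention, immaterial
under continuous models. The temporal split orders patients by surgery
date and cuts between patients where the cumulative measurement count
first reaches the target fraction, so no patient straddles the split.
Per-centile z-tests use the nominal-variance form
`z = (p̂ − p₀)/√(p₀(1−p₀)/n)` without continuity correction, two-sided.
Average bias is mean(observed − predicted median); negative values mean
observations sit below the curves. Cohort comparability uses Welch
t-tests (group sizes and variances differ) and a continuity-corrected
chi-square for the 2×2 sex table.

## Synthetic cohorts

The generator produces the data structure the analysis assumes, with
closed-form ground truth so recovery and calibration have exact oracles:

* median `μ(t) = 116 − 36·exp(−t/25)` degrees — ~80° immediately after
  surgery, ~105° at one month, ~115° at three, inside the typical
  clinical recovery bands;
* relative scale `σ(t)` log-linear from 0.18 (day 2) to 0.085 (day 120),
  giving an interquartile band of roughly 13–22° across the window;
* constant Box-Cox skewness ν = 2 (left skew: slow recoverers stretch the
  lower tail), response drawn from BCCG at the true curves (for NO/TF
  cohorts the relative scale is multiplied by μ to give degrees);
* visits: 40% of patients enter observation on days 2–7 and the rest
  uniformly on days 8–110 — reflecting patients who begin rehabilitation
  elsewhere and appear in a clinic network mid-recovery, which is what
  gives real datasets of this kind ~3 observations per patient *and*
  day coverage of the whole window; subsequent visits every 3–4 days;
  per-visit dropout hazard 0.30; at most 10 visits, truncated at day
  120. Defaults yield ≈ 1,600 observations from 500 patients.
* optional multiplicative per-patient effect on μ (log-normal,
  `patient_effect_sd`); zero by default, so draws are exactly i.i.d.
  from the configured family.

What passing tests on these cohorts do **not** show about clinical data:
real flexion is recorded in whole (sometimes half) degrees by different
therapists; dropout is informative (fast recoverers discharge early);
within-patient correlation is certainly nonzero; and the true centile
curves need not follow an exponential-plateau shape. The generator
checks structure and statistical machinery, not clinical effect sizes.

## Problem sizes and numerical choices

Simulation-based checks use 500-patient cohorts (≈1,600 observations,
the scale of the motivating application) for recovery and temporal
validation, 150-patient cohorts for the family-selection and
hyperparameter-search experiments, 50,000 draws for coverage
calibration, and 10–20 seeded replicates per experiment. Spline edf
tolerance 1e-3; density/quantile consistency ~1e-6; chart CSV written at
10 significant digits (round-trips at 1e-9). Degenerate inputs:
noiseless responses drive σ̂ to the log-link clamp without disturbing the
median curve; duplicate same-day measurements are kept and reported;
empty filter results warn rather than fail.

## Known limitations

* A calibrated chart read at 7 centile levels will fail at least one
  nominal-variance z-test in roughly one replicate in five at n ≈ 400 —
  joint non-significance of many correlated tests is a stricter event
  than per-level calibration, and validation reports should be read
  per-level (this mirrors the behaviour of reference-chart validation
  generally, where one of several centile tests reaching p ≈ 0.03 is
  unremarkable).
* Under left skew (ν > 1) the median predictor carries an intrinsic
  average bias E[y] − median ≈ −μσ²(ν−1)/2 ≈ −1° at the default
  conditions; bias near −1° to −3° is therefore expected even from a
  perfect chart and is not evidence of misfit.
* No random effects, no covariates beyond time, no conditional
  (longitudinal) centiles: the chart is cross-sectional by design.
* Fitting uses numerical derivatives; it is robust but roughly 2–5×
  slower than hand-coded score functions would be (a 1,600-observation
  BCCG fit takes ~0.3 s).
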