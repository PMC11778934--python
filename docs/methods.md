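# Methods

## Scope and model

`valsampsize` computes the minimum sample size for an **external validation
study** of an existing clinical prediction model — a study that estimates how
well a previously developed model performs in new data. The premise is that
the study should be sized so that each key performance measure is estimated
with a prespecified precision, rather than by events-based rules of thumb
(e.g. "100 events and 100 non-events"), which ignore the model, the outcome
proportion and the case-mix distribution.

Throughout, a 95% confidence interval width is defined operationally as
`2 × 1.96 × SE`, and each criterion returns the smallest integer n whose
anticipated SE meets the implied target. The study requirement is the
maximum across criteria (the *binding* criterion). All calculations are
prospective: they consume anticipated ("assumed true") performance values,
ideally optimism-adjusted estimates from the development study, and no data.

## Continuous outcomes

Inputs: anticipated `R²` (proportion of outcome variance explained in the
validation population), outcome variance `var(Y)` (or SD), anticipated
calibration-in-the-large `a` (default 0) and calibration slope `b`
(default 1, i.e. a well calibrated model), and width targets. The residual
variance implied by these assumptions is `σ²ₑ = var(Y)(1 − R²)`.

1. **R²**: `SE(R̂²) = sqrt(4 R² (1 − R²)² / n)` (large-sample variance of a
   squared correlation).
2. **CITL** (mean observed − mean predicted): `SE = sqrt(σ²ₑ / n)`.
3. **Calibration slope** (observed on predicted): the calibration
   regression gives `SE(b̂) = sqrt(σ²ₑ / ((n − 1) · var(Ŷ)))` with
   `var(Ŷ) = R² var(Y) / b²`, hence `SE = sqrt(b²(1 − R²)/((n − 1) R²))` —
   `var(Y)` cancels and the `n − 1` small-sample form matters (the naive
   `n` form understates the requirement by a couple of participants).
4. **Residual variance**: rather than a CI width (the measure is
   scale-dependent), the criterion bounds the *multiplicative margin of
   error* of the residual SD. With residual sum of squares on `ν = n − 2`
   degrees of freedom (intercept + slope of the calibration model),
   `MMOE(n) = max( sqrt(ν/χ²₀.₀₂₅,ν), sqrt(χ²₀.₉₇₅,ν/ν) )`, and the default
   target is 1.1 (a 10% margin). This yields n = 235 for every design —
   deliberately invariant to `R²` and `var(Y)`.

**Target-SE convention.** Width targets for criteria 1–3 are converted to SE
targets *quoted to four decimal places* (width 0.3 → SE 0.0765, width 0.1 →
SE 0.0255, width 5 → SE 1.2755), matching how these targets are stated in
practice. The convention is visible only in edge cases (e.g. the R² = 0.30
sensitivity analysis, where it gives 905 rather than 904).

## Binary outcomes

Inputs: anticipated outcome proportion `φ`, c statistic, O/E ratio (default
1), calibration slope (default 1), width targets, optional probability
thresholds for net benefit, and the anticipated distribution of the model's
predicted values (below).

1. **O/E**: `SE(ln O/E) = sqrt((1 − φ)/(n φ))`; the CI is
   `O/E · exp(±1.96 SE)` and the width target applies to this asymmetric,
   back-transformed interval. (This log-scale convention, with a direct
   integer search on the width, reproduces the published requirement of 423
   at φ = 0.43 and width 0.22.)
2. **Calibration slope**: the logistic calibration model
   `logit P(Y=1) = α + β·LP` is, under the assumed truth `(α, β)`, expected
   to carry per-observation Fisher information
   `I = E[q(1−q) · (1, LP; LP, LP²)]` with `q = expit(α + β·LP)`, the
   expectation taken over the LP distribution. Then
   `SE(β̂) = sqrt(I₀₀ / (n(I₀₀I₁₁ − I₀₁²)))`. When an assumed slope ≠ 1 is
   supplied, the intercept is solved so the implied event proportion still
   equals `φ`.
3. **c statistic**: Newcombe's approximation,
   `var(ĉ) = c(1−c)[1 + (n/2 − 1)((1−c)/(2−c)) + (n/2 − 1)(c/(1+c))] /
   (n² φ(1−φ))`, solved by integer search (it is not closed-form invertible
   in n).
4. **Standardised net benefit** at threshold t:
   `sNB = sens − w(1 − spec)`, `w = ((1−φ)/φ)(t/(1−t))`, with sensitivity
   and specificity computed as expectations over the LP distribution under
   the assumed truth (classification by the model's predicted probability;
   event status by the true risk). The variance is the delta-method result
   of Marsh et al. for the plug-in estimator with `sens`, `spec` and `φ`
   all estimated:
   `n·var(ŝNB) = sens(1−sens)/φ + w² spec(1−spec)/(1−φ) + w²(1−spec)²/(φ(1−φ))`.
   We re-derived this expression as the full multinomial delta method over
   the 2×2 classification table, and the test suite verifies it directly
   against the empirical SD of the plug-in estimator over thousands of
   simulated validation datasets.

Expected events are reported as `round(n·φ)` (nearest integer); integer
searches start at a floor of n = 20 (binary) / n = 10 (continuous), bracket
by doubling and finish by bisection, guaranteeing minimality (criterion met
at n, violated at n − 1) for these monotone SE functions.

## The linear-predictor distribution

Criteria 2 and 4 need the distribution of predicted values. Supported
specifications:

* `beta_probability(a, b)` — a beta distribution of predicted probabilities
  (typically fitted by eye, or with the provided least-squares helper, to a
  published histogram); implied event proportion `a/(a+b)`;
* `normal_logit(mean, sd)` — a normal linear predictor;
* `cstat_implied(φ, c)` — a last-resort binormal construction: log-odds
  normal with common variance and different means by outcome status.
  Requiring the implied c statistic to equal `c`, the event proportion to
  equal `φ`, and self-consistency of the risks (true slope 1) gives the
  closed form `δ = 2·Φ⁻¹(c)²`, variance `δ`, means `logit(φ) ∓ δ/2`. This
  is the analytic fixed point of the iterative matching procedure used
  elsewhere, so the construction is deterministic; the empirical c of large
  samples recovers the input (tested to ±0.005).
* a two-component log-odds mixture for histograms stratified by outcome
  status (advanced; its implied prevalence should be checked against the
  design value, which the design object enforces to a 0.02 tolerance).

Expectations default to adaptive quadrature (on the probability scale for
the beta family, on the log-odds scale otherwise, with panels split at
threshold discontinuities; relative tolerance 1e-6). If quadrature fails to
converge, a Monte-Carlo fallback with 1,000,000 draws and a fixed documented
seed is used and the method is recorded on the distribution object. In
practice every expectation used by the criteria resolves by quadrature, so
the returned sample sizes are deterministic; reported requirements therefore
do not wobble with simulation seeds (implementations that evaluate these
expectations by simulation can differ by a few participants, e.g. printing
2137 where quadrature gives 2135 for the slope criterion at width 0.2).

## Fixed-n (precision) mode

When an existing dataset of known size is to be obtained instead of new
recruitment, `precision_for_n_*` inverts each criterion: using the same SE
engines it reports the anticipated SE and 95% CI of every measure at the
given n. Known dataset characteristics (observed outcome variance, observed
prevalence, and so on) can be supplied as overrides so the anticipated
precision conditions on them. Round-trip consistency with the forward
criteria (target met at the returned n, violated at n − 1) is tested.

## Calibration-curve stability simulation

Precise slope and intercept estimates do not guarantee stable calibration
*curves*, so the package also implements the simulation check: draw
`replicates` (default 100) synthetic validation datasets of a candidate
size, fit a flexible calibration curve to each, overlay them, and summarise
the pointwise spread. The generator reproduces exactly the conditions
assumed by the sample size calculation — predicted values from the design's
LP distribution (binary) or normal with variance `R²·var(Y)` around the
anticipated outcome mean (continuous), and outcomes generated from the
assumed truth (by default a well calibrated model: Bernoulli at the
predicted probability, or predicted value plus a normal residual with
variance `var(Y)(1 − R²)`).

Numerical choices: curves are logistic regressions on a restricted cubic
spline of the linear predictor (4 knots at the 5/35/65/95% quantiles of the
assumed LP distribution, fixed across replicates) for binary outcomes, and
loess for continuous outcomes; the grid is 101 points spanning the central
98% of the predicted-value distribution (extremes are excluded because
spread there is dominated by extrapolation); the envelope is the pointwise
2.5–97.5% band across replicates; replicates whose fit fails (e.g.
separation at small n) are dropped and counted, with an error above a 5%
failure rate. Region summaries report the maximum envelope width within
user-specified predicted-value intervals (regions containing clinically
relevant thresholds) with an optional acceptability flag.

What the simulation does *not* emulate: real case-mix heterogeneity,
miscalibration shapes beyond a linear intercept/slope distortion, clustered
or missing data, and uncertainty in the assumed inputs themselves. Passing
stability checks therefore demonstrate sampling variability under the
assumed design, not robustness to wrong assumptions.

## Known limitations

* The sNB delta-method SE is slightly optimistic at very small n (≈11% at
  n ≈ 37 in the worked example, < 2% by n ≈ 200); the criterion can return
  very small n at extreme thresholds, and such results should be read as
  "this measure is not the binding constraint" rather than as a precise
  requirement. Published figures for this criterion computed with other
  tools can differ substantially (see the test suite's annotations).
* Newcombe's c-statistic SE is an approximation; the empirical SE agrees
  to ~15% under the binormal construction.
* The c-statistic-implied LP construction assumes binormal, equal-variance
  log-odds with a true slope of 1; it can be a poor approximation when
  those assumptions fail, and no diagnostic for that is provided (none is
  established). Prefer a distribution read from the development study.
* Time-to-event outcomes, model updating, decision-curve analysis across a
  threshold continuum, and missing-data methods beyond sample-size
  inflation are out of scope.
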