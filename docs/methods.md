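# Methods

## Model family and estimation

The package fits six conditional-process structures linking a focal
meteorological antecedent X, a pollutant mediator M and a daily count
outcome Y, with optional moderators W and Z.  Every structure is a pair
of linear equations estimated independently by ordinary least squares on
the same sample; the equations differ only in which product terms
appear:

| structure | X→M path            | X→Y (direct) path   |
|-----------|---------------------|---------------------|
| 1         | unmoderated         | unmoderated         |
| 2         | unmoderated         | moderated by W      |
| 3         | moderated by W      | unmoderated         |
| 4         | moderated by W      | moderated by W      |
| 5         | moderated by W, Z   | unmoderated         |
| 6         | moderated by W, Z   | moderated by W, Z   |

Assumptions are those of OLS mediation analysis: linear effects,
exogenous regressors, homoscedastic Gaussian-ish errors, and — notably
for daily series — independent errors.  Serial correlation in daily
surveillance data is *not* corrected for; estimates remain consistent
but analytic intervals can be anticonservative for strongly
autocorrelated residuals.  Counts are treated as a continuous outcome
rather than via a Poisson/negative-binomial likelihood.  Dates are
metadata only: models are contemporaneous, with no lag structure.

All analysis variables (X, M, W, Z and by default Y) are mean-centered
before product terms are formed; the products themselves are not
re-centered.  This is the standard convention that makes the X
coefficient the effect at average moderator values.  Fitted values are
invariant to the centering choice (the design spans are identical);
coefficients are re-parametrised by it, which is why published
coefficient tables must be read on their stated centering.

Coefficient covariance is σ̂²(XᵀX)⁻¹ with the unbiased σ̂² on n−p
degrees of freedom per equation.  A condition-number guard (10¹⁰ on
each design matrix) converts near-collinearity into an explicit error
naming aliased columns where it can find them.

## Effects and inference

Direct and indirect effects are linear functions of the moderators:
`direct(W,Z) = c_x + c_xw·W + c_xz·Z` and
`indirect(W,Z) = (a_x + a_xw·W + a_xz·Z)·b`, with slopes fixed at zero
for absent product terms.  The index of moderated mediation is the
slope of the indirect effect in one moderator (`a_xw·b` or `a_xz·b`).
Effects are probed by default at the 16th/50th/84th percentiles of each
moderator's centered sample.

Single coefficients (hence conditional direct effects at fixed
moderator values) get two-sided t intervals.  Indirect effects are
products of coefficients from two equations, with skewed finite-sample
distributions, so they get percentile-bootstrap intervals: rows are
resampled with replacement, both equations re-estimated per replicate
(including the re-centering step, so the replicate pipeline matches the
estimation pipeline), and the interval is the empirical (α/2, 1−α/2)
quantile pair (numpy's default linear interpolation).  The default is
5000 replicates, plain percentile (no bias correction) — the simplest
member of the bootstrap family, documented rather than hidden.
Replicates with singular resampled designs (condition number of XᵀX
above 10¹²) are dropped and counted, with a warning above 5%.  Case
resampling (not residual resampling) is used so the joint covariate
distribution is preserved.  The bootstrap refits run through a batched
normal-equations solver vectorised over replicates; an identity-resample
unit test pins it to the reference OLS path.

Model selection fits every candidate (structure, roles) combination,
records R² of both equations (`1 − SSE/SST`, the package's own
implementation, cross-checked against statsmodels), and ranks
combinations with significant overall F-tests by outcome-equation R²,
ties broken by mediator-equation R² then lower structure number.
Because structure 6's outcome design nests all the others, it can never
rank below them on the same data — selection among nested structures is
a description of explanatory gain, not a penalised comparison (AIC/BIC
are deliberately out of scope).  No multiplicity correction is applied
across the sweep.

## Synthetic data generator

The generator emulates ~1050 consecutive days (three seasons of a
winter-peaking epidemic in a polluted mid-latitude city):

| quantity | default | rationale |
|---|---|---|
| minimum temperature | 9.1 °C mean, ±12 °C annual amplitude, 3 °C daily noise, peak mid-July | matches the mean/SD/range of daily minima in the emulated setting |
| maximum humidity | 88 % mean, ±6 % amplitude, 6 % noise | high-humidity regime with realistic spread |
| pressure | 1016.3 hPa mean, ±10 hPa amplitude in antiphase with temperature, 4 hPa noise | winter highs, summer lows |
| mediator (AQI-like) | level 102, ε_M SD 35 | reproduces an overall index SD near 55 once the meteorological signal is added |
| mediator equation | a_x −4.0, a_w −0.25, a_z −1.7, a_xw −0.10, a_xz 0.08 | magnitudes of published daily fits |
| outcome (cases/day) | level 74, ε_Y SD 20 | overall SD near 30 |
| outcome equation | c_x −1.6, c_w −0.23, c_z 0.13, c_xw 0.005, c_xz −0.055, b 0.15 | direct-path magnitudes from published fits; b set to a clearly nonzero 0.15 so the mediation channel carries real signal for power and recovery studies (published point estimates of b are near zero and not significant — a generator with no channel could not validate indirect-effect machinery) |
| annual period | 365.25 days | fixed |

Covariates entering the true equations are sample-centered inside the
generator, so truth coefficients live on the scale the fitter
estimates.  The mediator enters the outcome equation as its centered
realisation.  Noise is Gaussian on both equations.  A count
post-process (clip at zero, round the outcome) is off by default so
recovery tests are exact-model tests; switched on for realism demos.

**Truth record.**  Slopes are reported exactly as configured.  The
intercept estimand under the package's centering absorbs a
data-dependent term (e.g. `−a_xw·mean(Xc·Wc)`, since product columns are
not re-centered), so the truth record reports, per dataset, the
*conditional estimand* of every coefficient: the projection of the
noise-free signal onto the fitted design.  The noise-free signal lies
exactly in the design span, so this projection is exact, OLS is
conditionally unbiased for it, and parameter-recovery comparisons are
like-for-like for every term including the constant.

**What the generator does not emulate**, hence what passing tests do
not show about real data: pollutant distributions are Gaussian rather
than right-skewed (a log-normal mediator-noise option is a possible
extension; synthetic indices can dip below zero, which the descriptive
AQI-level labelling clips), residuals are serially independent (real
daily series are autocorrelated), there are no epidemic transmission
dynamics or haze episodes, and counts are continuous unless the
post-process is enabled.  Calibration results certify the estimator
under its own assumptions, not robustness to their violation.

## Numerical choices and degenerate inputs

- Exactly noiseless mediators are unidentifiable territory: with
  ε_M ≡ 0 the mediator is an exact linear combination of the outcome
  design's other columns, making that design singular (the collinearity
  guard fires).  Interpolation-style checks therefore use a vanishing
  but nonzero ε_M, or set ε_Y = 0 at ordinary mediator noise, or force
  b = 0 when a genuinely constant bootstrap statistic is needed.
- Correlation screening: p-values from the exact t transform on n−2
  degrees of freedom; |r| = 1 maps to p = 0; zero-variance columns are
  an error naming the column.  Strength bands are half-open at 0.36 and
  0.68 so that every |r| ≤ 1 gets exactly one label (the underlying
  rounded convention leaves the gaps (0.35, 0.36) and (0.67, 0.68)
  undefined).
- Missing data: complete-case deletion at load time with a logged drop
  count; no imputation.
- Reported effect tables round to 4 decimals for display; internal
  values are full precision.
- All randomness flows through `numpy.random.default_rng` seeds;
  per-dataset and per-combination seeds are spawned from a root
  `SeedSequence` so experiments are reproducible and independent.

## Validation problem sizes

The acceptance suite runs, at the generator's default conditions
(n = 1050 days): 200 datasets for parameter recovery and coverage of
the direct-path coefficient; 500 null datasets (a_x = 0) and 200
alternative datasets at 1000 bootstrap replicates for type-I error and
power of the indirect-effect interval; and 100 datasets for structure
selection (200 replicates for the per-combination significance flags,
which the ranking does not use).  Recovery demands |bias| below three
Monte-Carlo standard errors per coefficient, coverage within
[0.92, 0.98], type-I error ≤ 7.5%, power > 80%, and the generating
structure top-ranked in ≥ 90% of sweeps.

## Known limitations

Beyond the generator gaps above: the six structures are the whole
candidate space (no multiple simultaneous mediators, no Johnson–Neyman
regions, no standardized effect sizes); inference is not robust to
heteroscedasticity (no HAC/robust standard errors); and R²-based
selection among nested models always prefers the largest structure
when all F-tests pass, so substantive interpretation should lean on the
effect estimates and their intervals, not the ranking alone.
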