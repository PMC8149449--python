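# Methods

## The prediction problem

The target quantity is the dim light melatonin onset (DLMO): the clock time
at which evening salivary melatonin rises past 2.3 pg/mL and stays there,
located by linear interpolation between the hourly samples bracketing the
crossing. A first crossing followed by a dip back below the threshold does
not qualify; a profile that starts at or above threshold, or never
qualifies, is *undetermined* (an error state, never a number). DLMO is the
reference against which both predictors are trained and scored, and it
feeds the clinical classification: *circadian* DSWPD if DLMO falls no more
than 30 min before (or any time after) the desired bedtime, *non-circadian*
otherwise. The −30 min boundary is classified circadian (inclusive
reading); a threshold crossing landing exactly on a sample value takes that
sample's time.

All clock quantities live on a linearized axis from 12.0 (noon) to 36.0
(next noon), so that evening–overnight spans (DLMO ranges past midnight in
this population) are continuous. Means, regressions and prediction errors
are computed on this axis; differences are wrapped to (−12, 12] h.

## Input data and preprocessing

A recording is ~7 days of 1-min wrist actigraphy — white-light illuminance
(lux) and a scored binary sleep/wake state — plus a diary of nightly bed
and wake times and one desired bedtime. Sleep scoring is consumed as given.

Diary reconciliation: when the diary bedtime precedes the onset of the
night's sustained low-light sleep run by ≥ 60 min, bedtime moves to that
onset; when the diary wake time disagrees with the onset of the sustained
wake/light-rise run ending the night by ≥ 60 min (either direction), wake
moves to that onset. "Sustained" is operationalized as a run of ≥ 30 min of
sleep-scored epochs below 10 lux (mirror image for wake); both thresholds
are configurable. The published procedure used consensus visual
inspection, which cannot be reproduced exactly; the thresholded rule is a
deterministic stand-in, and it is idempotent by construction. Nights with
no detectable sleep episode are flagged invalid; summary bed/wake times
require ≥ 5 valid nights.

Light cleaning: wake epochs strictly below 1 lux are removed as
covered-device artifacts (a measured 1.0 lux is kept); light during scored
sleep is set to 0 lux (closed eyelids). The cleaned series is binned
(1–120 min, mean or max; bins anchored at clock midnight so repeated-day
inputs stay clock-aligned), missing runs up to a configurable cap (1–6 h)
are filled with either 0 lux or the mean of the preceding 2 h (0 when no
prior data exists, e.g. a gap at the series start), and the longest
gap-free run — trimmed to whole 24-h days anchored at the run's first
epoch — becomes the model input. A recording that cannot supply one whole
day is excluded with an explicit log entry.

## The dynamic pacemaker model

State: pacemaker pair (x, xc) on a higher-order van der Pol limit cycle
plus the activated photoreceptor fraction n ∈ [0, 1] (Process L). With
time in hours:

    alpha(I) = alpha0 * (I/I0)^p * I/(I + 100)
    dn/dt    = 60 * (alpha*(1-n) - beta*n)
    B        = G * alpha * (1-n) * (1 - b*x) * (1 - b*xc)
    Ns       = rho * (1/3 - s)          s = 1 during sleep
    dx/dt    = (pi/12) * (xc + mu*(x/3 + 4x^3/3 - 256x^7/105) + B + Ns)
    dxc/dt   = (pi/12) * (q*B*xc - x*((24/(c*tau))^2 + kappa*B))

Defaults: alpha0 = 0.05 min⁻¹, beta = 0.0075 min⁻¹, p = 0.5, I0 = 9500 lux,
mu = 0.23, q = 1/3, kappa = 0.55, rho = 0.032; tau = 24.15 h, b = 0.40,
G = 37 (trained values for the delayed-phase population: tau = 24.40,
b = 0.45, G = 37). The non-photic drive is ungated by default; a gated
variant that suppresses it during the pacemaker's subjective night sits
behind `nonphotic_gated` for sensitivity analyses. Note the PRC-shape
constant of the photic drive is called *b* here; the distinct coefficient
multiplying B in dxc/dt is named *kappa* to avoid a symbol collision.

**Period calibration.** The correction constant c is not free: it is pinned
by the requirement that the model free-run in darkness (I = 0, constant
wake) with period equal to tau. Under the package's fixed-step RK4
discretisation the value satisfying this is c = 0.99160, obtained by secant
root-finding on the simulated period at tau = 24.40
(`calibrate_period_constant`); the residual period error at tau = 24.15 is
~0.004 h, within the 0.01-h calibration band asserted by the tests. The
calibration property, not the constant, is the contract — anyone changing
the integrator or stiffness should re-run the calibration.

**Integration.** Fixed-step 4th-order Runge–Kutta, step = min(1 min, bin
width), forcing (lux and sleep state) held constant within each bin;
deterministic. Initial state (x, xc, n) = (−1, 0, 0.5); the input segment
is repeated end-to-end to ≥ 60 days so the model reaches a steady entrained
cycle, which makes the initial state immaterial (tested: two distant
on-cycle starts land within 5 min of DLMO; 60 vs 90 days differ by < 2 min).

**Phase read-out.** CBTmin is the local minimum of x each cycle, refined by
quadratic interpolation between the 1-min samples (no additional phase
offset — any constant offset is absorbed by training against DLMO through
the fixed 7-h angle). DLMO events are CBTmin − 7 h; the prediction is the
mean clock time of the final input repetition's events (one per day; taken
as the last segment-days events, since the final cycle's minimum can fall
just past the simulation end).

**Training.** Exhaustive grid search minimising training RMSE of predicted
vs. measured DLMO over tau (24.15 upward in 0.05-h steps, capped at 25.40),
b (0.40 upward in 0.05 steps, capped at 0.80), G (37 × 1.05^j, j ≤ 10), bin
width/statistic, gap policy and gap cap. The caps are package choices (the
training protocol states only lower bounds) and are configurable. Ties
break toward the configuration closest to the defaults, compared
lexicographically in the order (tau, b, G, bin, stat, policy, gap).
Recordings that fail preprocessing under a particular configuration are
skipped for that configuration and counted in `n_used`.

## The statistical model

CBTmin is anchored for the entire sample at the group-mean DLMO + 7 h
(default anchor 22:10 → 5:10; the pipeline recomputes it from the analysis
sample's measured DLMO, mirroring the published procedure). The delay zone
is [CBTmin − 6 h, CBTmin) and the advance zone (CBTmin, CBTmin + 6 h]. For
each noon-anchored calendar day (noon anchoring keeps the overnight delay
zone unsplit) the mean of log₁₀(max(lux, 0.001)) over non-missing cleaned
epochs is computed per zone; a zone-day needs ≥ 75% non-missing epochs (a
package choice guarding means computed on slivers), and a participant needs
≥ 5 valid days, which are then averaged into one delay and one advance
value. Covariates: age (years), sex (female = 1), mean actigraphic
bed/wake times (linearized hours), and chronotype category (composite
morningness–eveningness score 16–30 = definite evening = 1; 31–41 =
moderate = 0). The codings are package choices; the fit is equivalent
either way. DLMO is regressed on these seven predictors by OLS
(statsmodels); rank-deficient designs are rejected with the offending
columns named.

The train/test split is 50/50, stratified by study site, seeded; both
models consume the identical split. Odd-sized sites hand their extra
member to the currently smaller half (seeded coin flip on ties).

## Evaluation

Errors are (predicted − actual) in minutes. Reports carry mean error, mean
absolute error, RMSE (each with SD), and counts/percentages within ±0.5,
1, 1.5, 2 and > 2 h. Band shells are half-open with edges belonging to the
tighter band ("within ±1 h" means |error| ≤ 60 min), so cumulative
percentages are monotone and reach 100. Pearson r and the slope (with SE)
of predicted on actual come from simple regression; correlations are
compared with the independent-samples Fisher r-to-z formula

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)),

which is used even when the two models share a test set because it
reproduces the published comparison exactly; strictly, dependent
correlations would need a Steiger-type correction, and the package
documents this caveat rather than silently substituting it. Slopes are
compared by z = (b1 − b2)/√(SE1² + SE2²). The bedtime heuristic predicts
DLMO as mean actigraphic bedtime − 2 h. Classification scoring uses
circadian as the positive class (sensitivity, specificity, F1, accuracy).

## The synthetic cohort generator

The generator emulates the *statistical structure* of the clinical cohort,
not its individual physiology. Per participant (all draws from a
per-participant substream hashed from the participant id, so cohorts are
reproducible and order-independent):

- mean bedtime ~ N(0:41, 1:19); DLMO = bedtime − gap with
  gap ~ N(2:34, 0.565 h), which yields DLMO ~ 22:07 ± 1:26 by construction;
  sleep duration ~ N(8:05, 0.5 h) giving wake ≈ 8:46; desired bedtime =
  DLMO + N(−0:19, 1:17) (the published desired-bedtime phase-angle
  distribution); age truncated-normal 30.1 ± 10.7 on [16, 64]; P(female) =
  0.545; P(definite evening chronotype) = 0.851; three equiprobable sites.
- nightly bed/wake times jitter around the means (SD 0.4 h); the diary
  reports them with 10-min noise.
- light: 1-min epochs; sleep reads 0 lux; wake draws log-normal indoor
  illuminance (median 150 lux), Poisson daylight bursts (median 5000 lux),
  and a ×0.2 dim factor in the 2 h before bed; floor 1.5 lux so the clean
  generator itself never triggers the covered-device rule.
- artifacts (defaults chosen as a realistic field burden): 0.5
  covered-device episodes/day (wake lux < 1, mean 30 min — removed by
  cleaning) and 0.3 true gaps/day (mean 60 min).
- melatonin: hourly samples from 5 h before to 2 h after habitual bedtime;
  the noise-free profile rises linearly through (true DLMO, 2.3 pg/mL) at
  2 pg/mL/h above a 0.25 pg/mL daytime floor, so interpolation recovers the
  truth exactly; optional multiplicative log-normal sample noise.

Ground-truth modes: *phenomenological* (default; DLMO from the phase-angle
draw — model-agnostic) and *model_consistent* (DLMO = the dynamic model's
own prediction with a reference parameter set on the artifact-free
recording), the latter existing so parameter-recovery experiments have a
well-defined truth.

What passing tests on this generator do **not** show: real light exposure
has weather, season, and behavioural feedback (light avoidance in evening
types) that the log-normal/burst model lacks; real melatonin profiles have
assay noise and variable rise shapes; real sleep scoring errs. Recovery
results here certify the pipeline's correctness, not its field accuracy.

## Problem sizes and numerical choices

Simulations integrate 60 input days at a 1-min step (~86 400 RK4 steps,
a few ms with the numba-compiled kernel; a pure-Python fallback keeps the
package functional, slower, without numba). The recovery experiments in
the test suite use cohorts of n = 40 over 10 seeds with a restricted
(tau-only) grid, and the regression coverage experiment uses 200 replicates
of n = 500 drawn at the covariate level — sizes chosen to make the
statistical assertions sharp while the full suite stays fast. Epochs are
half-open [t, t + width); an epoch belongs to sleep if the sleep episode
covers its start; zone membership uses a 10⁻⁶-h tolerance against float
jitter on the minute grid.

## Known limitations

- Group-level parameters only; no per-individual fitting of tau or light
  sensitivity, so predictions regress extreme individuals toward the mean.
- Photopic lux at the wrist is the only light input; no melanopic weighting.
- The statistical model needs the sample's mean DLMO to anchor its zones.
- The diary-reconciliation thresholds stand in for a human consensus
  procedure and have not been validated against one.
- Time zones/DST transitions within a recording are not handled.
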