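# Methods

This note documents the models, numerical choices and limitations behind
`nestrec`. It is the package's own account of its science; every number in
it is computed by the test suite or `scripts/acceptance.py`, not asserted.

## Recess segmentation

A nest trace is a 1-minute temperature series. For each local calendar day
the segmentation threshold is `daily maximum − Δ` with Δ = 4.5 °C; a recess
is a maximal run of minutes *strictly below* the threshold lasting at least
3 min (1-min loggers cannot time bout edges better than ±1–2 min, so
shorter runs are noise). Three deliberate tie-breaks, fixed because the
underlying convention is otherwise ambiguous:

* a minute exactly at the threshold is incubation (strict inequality);
* a run that crosses midnight is evaluated entirely against its onset-day
  threshold and kept as one recess;
* gap minutes (missing records, never interpolated) terminate a run.

The daily threshold uses the maximum rather than the median because the
median collapses during long off-bouts: a day containing >720 sub-threshold
minutes has a "median incubation temperature" that is really ground
temperature, and the legacy rule (median − 3 °C, scored only on days with
median > 36 °C) then silently discards exactly the days that contain
extended recesses. The legacy rule is implemented (`method="median_drop"`)
for comparison, and `compare_methods` quantifies the concordance: on clean
traces the two rules match short recesses essentially one-for-one, while
planted multi-hundred-minute bouts are only captured by the max-drop rule.
The tests assert both behaviours.

Quality filters, each with a machine-readable reason code: nests monitored
< 24 h; days whose daily maximum falls below 37.5 °C (the 36 °C
incubation-quality floor plus a configurable 1.5 °C nest-vs-ground offset —
the offset is a named constant, not hard-coded arithmetic, because its
provenance is a convention rather than a measurement); days on a manual
erratic-pattern list; recesses overlapping recorded capture events.

Total daily recess duration (TDR) splits midnight-crossing bouts between
days, so per-nest `Σ daily TDR = total recess minutes` holds exactly and
daily TDR is bounded by 1440. The whole segmentation is checked against an
independent per-minute brute-force scan on randomized days.

## Short vs extended: the antimode threshold

Recess durations are strongly bimodal in log-minutes. The class boundary is
the antimode — the local minimum of a Gaussian-kernel density estimate
between the two modes — estimated on log-duration and back-transformed.

Bandwidth: durations are integer minutes, and at small bandwidths the log
scale resolves the integer spacing (log 3, log 4, …) into spurious ripple
modes, while large bandwidths visibly bias the antimode location (a
mid-bandwidth sweep during development moved the estimated antimode ~14 %
with near-zero variance). The default is therefore the *critical bandwidth*:
the smallest bandwidth at which the density has exactly two modes (mode
count is non-increasing in bandwidth for Gaussian kernels), found by
bisection from Silverman's rule. This mirrors the standard mode-tree
approach for mode counting and is robust to discretization; an explicit
bandwidth can be supplied instead. Peaks with prominence below 10⁻³ of the
density maximum are treated as numerical ripple. The KDE itself is binned
(2048-point grid, Gaussian filter), making a single estimate ~0.5 ms, which
the bootstrap relies on.

Ties: a duration exactly at the threshold is *extended* (the observed
extended class is defined from its minimum value upward).

Uncertainty: a nonparametric bootstrap (default 1000 resamples) with a
percentile 95 % CI. Each resample re-derives its own critical bandwidth,
warm-started from the full-sample value; holding the bandwidth fixed
instead was measured (during development, on the acceptance mixture) to
undercover by a few points because it ignores bandwidth-selection
variability. Resamples that are unimodal fail and are counted; more than
50 % failures aborts with an error. Resamples showing extra ripple modes do
not fail — the two most prominent peaks are used — since the mode structure
is established on the full sample and the bootstrap only measures location
uncertainty. Stratified estimation (year × site) is available, with pooled
fallback for strata under 50 durations.

The acceptance experiment draws an equal lognormal mixture with log-modes
at 7 and 340 min (n = 5000), checks the estimator against an independent
direct-sum KDE minimum on a 0.01-log grid (±10 %), and verifies ≥90/100
coverage of the population antimode by the bootstrap CI.

## Covariates

* **Body condition** — scaled mass index: `SMI_i = m_i (L0/tarsus_i)^b`
  with `b = b_OLS / r` (standardized major axis) from ln mass on ln tarsus,
  and `L0` the arithmetic mean tarsus by default (configurable to match a
  published reference length). One value per bird: birds are captured once
  and population-level seasonal mass change is assumed absent.
* **Pre-recess temperature** — mean of the site ground series (per-minute
  mean over inactive-nest loggers; combining rule configurable) over the
  half-open window `[t0 − h, t0)` for h ∈ {1, 2, 6, 12, 24}; the onset
  minute is excluded. Windows under 50 % coverage give a missing value and
  the recess drops out of models using that window.
* **Period** — night is 17:00–24:00 ∪ 00:00–09:00 local (the birds'
  behavioural night under permanent daylight): 960 night + 480 day minutes.
* **Incubation date** — days since the nest's incubation start.

## Mixed models

Every model carries a nest-identity random intercept.

* **Occurrence** (extended vs short, binomial-logit): statsmodels has no
  maximum-likelihood binomial GLMM with a true log-likelihood, so the
  package implements one: the random intercept is integrated out by
  *adaptive* Gauss–Hermite quadrature (nodes re-centred at each group's
  conditional posterior mode with curvature rescaling, found by Newton
  steps; 15 nodes default). Plain prior-centred quadrature was tried first
  and is documented as inadequate: with ~400 observations per group and
  2 % event rates the integrand is ~5× narrower than the node spacing and
  the fit is badly biased. The adaptive version reproduces
  `lme4::glmer(nAGQ=25)` coefficients, σ and log-likelihood to ~10⁻³ on a
  shared fixture (a test runs the comparison through Rscript). Standard
  errors come from central-difference differentiation of the analytic
  gradient; the gradient treats the per-group adaptation as fixed, which
  is exact up to the (tiny) quadrature error.
* **Durations and TDR** (Gaussian): statsmodels `MixedLM`, always `reml=False`
  — AICs are compared across fixed-effect structures, which REML forbids.
  AIC is computed as `2k − 2ℓ` with k counting fixed effects plus both
  variance components. p-values use residual degrees of freedom, flagged as
  `df_method="residual"` in every fit: a Satterthwaite approximation is not
  provided by the backend and was judged not worth hand-rolling for models
  whose inferences here never hinge on small-sample df (every family fits
  on hundreds of observations). Optimizer fallbacks (lbfgs → powell → nm → cg) handle
  boundary fits where the random-effect variance collapses; such fits are
  retained and flagged `singular`.

Numeric predictors are Z-scored before fitting; each fit stores the
(mean, sd) pairs so slopes are reported per raw unit (`raw_slope`), and
back-transformed slopes are invariant to affine rescaling of the inputs
(property-tested).

**Variance explained** — marginal R² = var(Xβ̂)/(var(Xβ̂) + σ²ᵤ + σ²ₑ),
conditional adds σ²ᵤ to the numerator; for the logit family σ²ₑ = π²/3
(latent-scale residual variance).

**Window selection** — one fit per candidate window on the *identical*
complete-case intersection (differing n makes AIC meaningless and raises a
hard error); windows within ΔAIC ≤ 2 of the best are reported as equally
supported.

**Interaction selection** — the temperature × body-condition spec is
retained when it has the higher marginal R² (ties break to the simpler
model). Both fits and AICs are always reported.

**Simple slopes and Johnson–Neyman** — for a fitted interaction, the
conditional temperature slope at moderator value m (Z scale) is
`s(m) = b_T + b_TM·m` with `Var s(m) = V_T + m²V_TM + 2m·Cov`; JN bounds
are the real roots of `s(m)² = t*² Var s(m)` (closed form, checked against
the quadratic formula to 10⁻⁶), reported in raw moderator units, with the
sign of the leading coefficient deciding whether significance holds outside
or inside the interval (or everywhere/nowhere for complex roots). Probe
slopes are reported at the minimum, median and maximum observed moderator.
The FDR adjustment evaluates the conditional-slope p-values at every
observed moderator value, applies Benjamini–Hochberg at level α, converts
the resulting p-value cutoff back into an inflated critical value t*₍FDR₎,
and re-solves the quadratic; both adjusted and unadjusted bounds are always
reported. If no observation survives BH, the adjusted bound is reported
absent.

**Occurrence effect size** — "relative change in extended-recess risk per
+1 °C" is ambiguous between scales, so both are computed: the odds scale
(`exp(b_raw) − 1`, constant) and the probability scale (mean relative
change in predicted probability per +1 °C over the observed temperature
range, other predictors at reference). At 2 % event rates they nearly
coincide.

## The synthetic study

The generator is the package's stand-in for field data and defines the
conditions every experiment runs under. Defaults (all configurable):

* **Ground temperature**: mean 9 °C, 5.5 °C diurnal half-range peaking at
  14:00, AR(1) minute noise (φ = 0.95, sd 0.5) and an AR(1) day-scale
  synoptic offset (sd 3.5, φ = 0.65), giving minute values spanning roughly
  −3…22 °C over a 10-day window — comparable to a high-Arctic breeding
  season.
* **Nest thermal process**: 38 °C incubation baseline, 0.25 °C sensor
  noise; during a recess the nest temperature relaxes exponentially toward
  ground temperature with a 1-min time constant and rewarms with a 0.5-min
  constant on return. With a >8 °C nest–ground gap the first off-minute is
  already >4.5 °C below baseline, so every planted bout ≥3 min is
  detectable with ±1-min endpoints — the basis of the recovery criterion.
* **Bout process**: per-minute onset hazard 0.056 in daytime, ×0.2 at
  night, 5-min refractory after each bout; this yields ≈20 recesses per
  nest-day (renewal expectation in `expected_recesses_per_day`), with a
  biparental preset (~9–10/day) for strategy-assignment tests.
* **Occurrence**: extended with probability
  `logit⁻¹(−2.2 − 0.22·T₁₂ + u)`, u ~ N(0, 1.2²) per nest. The −0.22/°C
  log-odds slope corresponds to ≈20 % lower odds per +1 °C; the intercept
  puts the extended fraction at ~2–3 %.
* **Durations**: short = lognormal(log 7, 0.7) (≥3 min); extended =
  lognormal(log 340, 0.32) plus a linear shift
  `−7·(T₆−9) − 3·(BC−57.8) + 0.82·(T₆−9)(BC−57.8) + u`, u ~ N(0, 25²),
  rejection-sampled above 120 min (a hard clip leaves an atom at 120 that
  shows up as a spurious density mode). The centered parametrization makes
  −7 the slope at reference condition and gives ≈−20 min/°C at the poorest
  condition and ≈+1 at the best.
* **Body condition**: N(57.8, 5.5²) per nest, encoded into morphometrics
  (tarsus N(24.5, 0.8²), mass from an isometric exponent of 3) so the SMI
  computation can re-derive it (r > 0.95 in tests).

The first simulated day is a warm-up (no planted bouts) so 12/24-h windows
always exist. `simulate_recess_table` is a fast path that draws from the
same hazard/occurrence/duration processes without the minute-level thermal
simulation; model-recovery experiments use it so that 20-replicate designs
stay inside a normal test run. Experiment sizes: recovery/conservation use
12 nests × 8 days (~2 400 planted bouts); the occurrence experiment 63
nests × 6 days (~8 000 recesses) per replicate; the interaction experiment
the ~190 extended recesses per replicate that this produces.

What the generator does *not* emulate: weather-driven hazard modulation
(rate and occurrence are linked to temperature only through the extended
branch), egg-cooling physics (exponential relaxation is a stand-in),
observer effects, logger drift, multi-year structure, or predation-driven
truncation of monitoring. Passing tests therefore demonstrate that the
pipeline recovers what its own processes plant under realistic noise — not
that field data meet these assumptions.

A development note on calibration: the initial ground-weather defaults gave
a 6-h window temperature SD of ~2.5 °C, much narrower than the conditions
the analysis is meant to emulate; under them the duration interaction was
so underpowered at n ≈ 190 that a Johnson–Neyman bound rarely existed. The
defaults above restore the intended regime (duration-model marginal
R² ≈ 0.12; a JN bound in most replicates near body condition ~60).

## Determinism and seeds

All randomness flows through `numpy.random.Generator` objects derived from
a single integer seed via `SeedSequence.spawn`; identical (params, seed)
reproduce traces bit-for-bit, and the pipeline report is JSON-identical
across reruns. `scripts/acceptance.py` derives everything from `--seed`.

## Known limitations

* The strategy discriminant (uniparental vs biparental from daily recess
  statistics) requires user-supplied coefficients; the published equation
  is not reproduced here, so the package ships the scoring/changepoint
  machinery and tests it with a discriminant fitted on its own generator.
* LMM p-values use residual df (see above); GLMM inference is Wald/normal.
* The bootstrap CI for the antimode is percentile-based; for heavily
  unbalanced mixtures (extended fraction ≪ 1 %) resample failures rise and
  the CI degrades gracefully but widens.
* `read_logger_csv` handles CSV exports (canonical and TinyTag-style
  dialects); proprietary binary logger formats are out of scope.
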