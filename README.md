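# nestrec

Detection, classification and modelling of incubation recesses from nest
thermologger records of Arctic-breeding shorebirds.

## The problem

Incubating shorebirds leave the nest briefly to forage ("recesses"); the
nest temperature, logged once per minute by a thermistor in the nest cup,
drops while the bird is away. Most recesses last minutes, but uniparental
incubators occasionally take *extended* recesses of several hours — a shift
toward self-maintenance under cold weather or poor body condition that has
large consequences for daily nest attentiveness. `nestrec` implements the
full analysis chain for this behaviour:

1. **Segmentation** — a recess is a maximal run of minutes strictly below
   `daily max − 4.5 °C` (onset-day threshold), lasting ≥ 3 min. The legacy
   rule (`daily median − 3 °C`, valid only on days whose median exceeds a
   36 °C quality floor) is provided for comparison; it fails for extended
   recesses because long off-bouts drag the daily median itself below the
   floor. Quality filters: ≥ 24 h monitoring, 37.5 °C daily-maximum floor,
   manual erratic-day and capture-event exclusions.
2. **Classification** — recess durations are bimodal on the log scale
   (modes near 7 and 340 min). The antimode of a Gaussian-kernel density
   estimate (critical bandwidth for exactly two modes) is the short/extended
   boundary, with a 1000-iteration nonparametric bootstrap 95 % CI,
   optionally stratified by year × site. The total daily duration of
   recesses (TDR) summarizes attentiveness per nest-day.
3. **Covariates** — mean ground temperature (from loggers in inactive
   nests) over the 1/2/6/12/24 h before each recess onset; body condition as
   the scaled mass index `SMI_i = m_i (L0 / tarsus_i)^b_SMA` with
   `b_SMA = b_OLS / r` from ln mass on ln tarsus; days since incubation
   start; day/night period (night = 17:00–09:00).
4. **Inference** — extended-recess *occurrence*: logistic GLMM with a nest
   random intercept, fitted by adaptive Gauss–Hermite maximum likelihood
   (authored in-package; validated against `lme4::glmer`); *durations* and
   *TDR*: Gaussian LMMs via statsmodels (ML). The pre-recess window is
   chosen by AIC on a common complete-case set; temperature × body-condition
   interactions are kept when they raise marginal R² (Nakagawa
   marginal/conditional R² reported for every fit) and probed with simple
   slopes and Johnson–Neyman intervals, with and without a
   false-discovery-rate–adjusted critical value.
5. **Synthetic data** — a minute-resolution generator with planted ground
   truth (diurnal + synoptic ground temperature, exponential nest cooling,
   hazard-driven bouts, logistic occurrence on the 12 h window, linear
   duration model with interaction) so every stage is testable end to end.

## Worked example

```python
from nestrec import GeneratorParams, RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=7,
                                generator=GeneratorParams(n_nests=20, days_per_nest=8),
                                n_boot=200))
th = report["threshold"]
print(th["antimode_min"], th["modes_min"], th["ci_95"])
```

Running `python examples/05_full_pipeline.py` (which does exactly this)
prints:

```
antimode: 116.7 min (modes 7.7 / 296.6, 95% CI [97.5, 128.4])
recesses: 3375, extended: 80 (2.4%)
occurrence model: best window 12 h, R2m 0.33, R2c 0.40
TDR: 596 min on days with an extended recess vs 201 min without
```

i.e. the duration mixture separates at ≈ 117 min; extended recesses are
rare (2.4 %) but roughly triple the daily off-nest time; and the 12 h pre-recess
temperature window — the generator's true driver — wins the AIC comparison.
The other scripts in `examples/` each demonstrate one capability
(segmentation, antimode + bootstrap, window selection, interaction probing).

A thin CLI wraps the same functions:

```bash
nestrec simulate --seed 42 --out bundle/
nestrec detect --in bundle/ --out det/
nestrec classify --recesses det/recesses.csv --boot 1000 --seed 42 --out cls/
nestrec run-all --seed 42 --boot 1000 --out run/     # everything + report.json
```

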