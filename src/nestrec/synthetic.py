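"""Synthetic thermologger traces with planted behavioural ground truth.

The generator emulates the Arctic-shorebird incubation regime so every
pipeline stage can be exercised, and parameter recovery checked, without
field data:

* ground temperature: diurnal sinusoid (afternoon peak) + AR(1) minute
  noise + day-scale synoptic offsets, spanning roughly -3 to 22 degC
  over a 10-day window;
* nest temperature: ~38 degC incubation baseline with small sensor noise,
  exponential relaxation toward ground temperature during recesses
  (time constant ``cooling_tau``) and rapid rewarming on return;
* recess initiation: per-minute hazard, reduced during the birds'
  "night" (17:00-09:00), with a short refractory period after each bout;
* bout type: extended with logistic probability in the mean ground
  temperature of the preceding 12 h (plus a nest random intercept) —
  the occurrence process;
* durations: a lognormal mixture with modes near 7 min (short) and
  340 min (extended), the extended component shifted linearly by the
  6 h pre-recess temperature, body condition and their interaction —
  the duration process.  Extended durations are truncated below at
  120 min (rejection sampling, so no probability atom at the bound).

Occurrence and duration are deliberately separate processes so each fitted
model has an identifiable generating parameter.  Defaults are calibrated to
the qualitative uniparental regime: ~20 recesses/day (hazard tuned for
~23.6 before bout-occupancy losses), ~2-3% of them extended, extended
durations with median ~340 min.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit

from nestrec.covariates import BirdMeasurement
from nestrec.timeseries_io import GroundSeries, NestMetadata, TemperatureTrace

DEFAULT_START = pd.Timestamp("2019-06-20 00:00")


@dataclass
class GeneratorParams:
    """All knobs of the synthetic study, with field-realistic defaults."""

    n_nests: int = 63
    days_per_nest: int = 10
    site: str = "SYN"
    # nest thermal process
    t_incubation: float = 38.0  # degC incubated baseline
    noise_sd: float = 0.25  # degC sensor/behavioural jitter
    cooling_tau: float = 1.0  # min, decay toward ground when off nest
    rewarm_tau: float = 0.5  # min, recovery on return
    # ground process (calibrated to a high-Arctic summer: minute values
    # spanning roughly 0-25 degC over a season)
    ground_mean: float = 9.0
    ground_amp: float = 5.5  # diurnal half-range
    ground_ar1: float = 0.95  # minute-scale autocorrelation
    ground_noise_sd: float = 0.5  # stationary SD of the AR(1) component
    day_offset_sd: float = 3.5  # synoptic (day-scale) weather SD
    day_offset_ar1: float = 0.65
    peak_minute: int = 840  # 14:00, early-afternoon maximum
    # recess initiation
    day_hazard: float = 0.056  # per-minute onset probability, daytime
    night_rate_factor: float = 0.2  # hazard multiplier 17:00-09:00
    refractory_min: int = 5  # min on nest between bouts
    # durations (log-minutes)
    short_dur_logmean: float = float(np.log(7.0))
    short_dur_logsd: float = 0.7
    ext_dur_logmean: float = float(np.log(340.0))
    ext_dur_logsd: float = 0.32
    ext_dur_min: float = 120.0  # lower censor for extended bouts
    # occurrence model: logit P(extended) = occ_beta0 + occ_betaT * T12 + u
    occ_beta0: float = -2.2
    occ_betaT: float = -0.22
    occ_nest_sd: float = 1.2
    # duration model (minutes), centered at (t_ref, bc_ref):
    # shift = bT*(T6-t_ref) + bBC*(BC-bc_ref) + bTxBC*(T6-t_ref)*(BC-bc_ref) + u
    dur_betaT: float = -7.0
    dur_betaBC: float = -3.0
    dur_betaTxBC: float = 0.82
    dur_t_ref: float = 9.0
    dur_bc_ref: float = 57.8
    dur_nest_sd: float = 25.0
    # body condition (scaled mass index, g)
    bc_mean: float = 57.8
    bc_sd: float = 5.5
    # morphometrics used to re-derive body condition via SMI
    tarsus_mean: float = 24.5
    tarsus_sd: float = 0.8
    sma_exponent_true: float = 3.0
    # biparental preset bits (used when uniparental=False)
    bi_day_hazard: float = 0.023
    uniparental: bool = True

    def __post_init__(self) -> None:
        if self.cooling_tau <= 0 or self.rewarm_tau <= 0:
            raise ValueError("thermal time constants must be positive")
        for name in ("noise_sd", "ground_noise_sd", "day_offset_sd",
                     "occ_nest_sd", "dur_nest_sd", "bc_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class StudyBundle:
    """Everything simulate_study produces: pipeline inputs + truth sidecar."""

    params: GeneratorParams
    seed: int
    ground: GroundSeries
    traces: list[TemperatureTrace]
    metadata: list[NestMetadata]
    morphometrics: list[BirdMeasurement]
    body_condition: dict[str, float]  # true per-nest SMI
    sex: dict[str, str]
    truth: pd.DataFrame  # planted recesses


def _night_mask(n_minutes: int, start: pd.Timestamp) -> np.ndarray:
    minute_of_day = (
        np.arange(n_minutes) + start.hour * 60 + start.minute
    ) % 1440
    return (minute_of_day >= 17 * 60) | (minute_of_day < 9 * 60)


def simulate_ground(
    params: GeneratorParams,
    site: str | None = None,
    n_days: int | None = None,
    seed: int | np.random.Generator = 0,
    start: pd.Timestamp = DEFAULT_START,
) -> GroundSeries:
    """Minute-resolution ground temperature for ``n_days`` days.

    Sinusoid peaking at ``peak_minute`` + stationary AR(1) minute noise +
    an AR(1) day-to-day synoptic offset.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_days = n_days if n_days is not None else params.days_per_nest
    n = n_days * 1440
    t = np.arange(n)
    minute_of_day = (t + start.hour * 60 + start.minute) % 1440
    diurnal = params.ground_amp * np.cos(
        2 * np.pi * (minute_of_day - params.peak_minute) / 1440.0
    )
    phi = params.ground_ar1
    innov_sd = params.ground_noise_sd * np.sqrt(max(1 - phi**2, 1e-12))
    noise = lfilter([1.0], [1.0, -phi], rng.normal(0, innov_sd, n))
    phi_d = params.day_offset_ar1
    d_innov = params.day_offset_sd * np.sqrt(max(1 - phi_d**2, 1e-12))
    day_off = lfilter([1.0], [1.0, -phi_d], rng.normal(0, d_innov, n_days))
    temps = params.ground_mean + diurnal + noise + np.repeat(day_off, 1440)
    return GroundSeries(site=site or params.site, start=start, temps=temps)


def _rolling_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Mean over the half-open window [t-window, t); NaN while warming up."""
    c = np.concatenate([[0.0], np.cumsum(x)])
    out = np.full(x.size, np.nan)
    out[window:] = (c[window:-1] - c[: -window - 1]) / window
    return out


def _extended_duration(
    params: GeneratorParams,
    t6: float,
    bc: float,
    u_nest: float,
    rng: np.random.Generator,
) -> float:
    dt = t6 - params.dur_t_ref
    db = bc - params.dur_bc_ref
    shift = (
        params.dur_betaT * dt
        + params.dur_betaBC * db
        + params.dur_betaTxBC * dt * db
        + u_nest
    )
    # rejection sampling keeps the lower bound without an atom at ext_dur_min
    for _ in range(50):
        base = np.exp(rng.normal(params.ext_dur_logmean, params.ext_dur_logsd))
        if base + shift >= params.ext_dur_min:
            return base + shift
    return params.ext_dur_min


def simulate_nest(
    params: GeneratorParams,
    ground: GroundSeries,
    body_condition: float,
    seed: int | np.random.Generator = 0,
    nest_id: str = "N001",
    *,
    uniparental: bool | None = None,
) -> tuple[TemperatureTrace, pd.DataFrame]:
    """Simulate one nest trace over the ground series span.

    Returns the trace and the planted-truth table (one row per bout:
    onset, duration, class, the pre-onset temperature covariates and the
    nest's body condition).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    uni = params.uniparental if uniparental is None else uniparental
    g = ground.temps
    n = g.size
    start = ground.start

    night = _night_mask(n, start)
    base_hazard = params.day_hazard if uni else params.bi_day_hazard
    hazard = np.where(night, base_hazard * params.night_rate_factor, base_hazard)

    t12 = _rolling_mean(g, 720)
    t6 = _rolling_mean(g, 360)
    u_occ = rng.normal(0, params.occ_nest_sd)
    u_dur = rng.normal(0, params.dur_nest_sd)

    candidates = np.where(rng.uniform(size=n) < hazard)[0]
    temps = params.t_incubation + rng.normal(0, params.noise_sd, n)

    rows = []
    t = 1440  # first day is warm-up so 12/24 h windows exist
    one_min = pd.Timedelta(minutes=1)
    while True:
        k = np.searchsorted(candidates, t)
        if k >= candidates.size:
            break
        s = int(candidates[k])
        T12 = t12[s] if np.isfinite(t12[s]) else g[max(s - 720, 0) : s].mean()
        T6 = t6[s] if np.isfinite(t6[s]) else g[max(s - 360, 0) : s].mean()
        if uni:
            p_ext = expit(params.occ_beta0 + params.occ_betaT * T12 + u_occ)
        else:
            p_ext = 0.0
        is_ext = rng.uniform() < p_ext
        if is_ext:
            dur = int(round(_extended_duration(params, T6, body_condition, u_dur, rng)))
        else:
            dur = int(round(np.exp(rng.normal(params.short_dur_logmean, params.short_dur_logsd))))
            dur = max(dur, 3)
        if s + dur + params.refractory_min >= n:
            break  # do not plant bouts truncated by the end of monitoring
        # off-nest: exponential relaxation toward the (moving) ground temp
        idx = np.arange(s, s + dur)
        gap = params.t_incubation - g[s]
        temps[idx] = g[idx] + gap * np.exp(
            -np.arange(1, dur + 1) / params.cooling_tau
        )
        # return: rapid rewarm toward the incubation baseline
        e = s + dur
        deficit = params.t_incubation - temps[e - 1]
        n_rw = min(int(np.ceil(6 * params.rewarm_tau)), n - e)
        ridx = np.arange(e, e + n_rw)
        temps[ridx] = (
            params.t_incubation
            - deficit * np.exp(-np.arange(1, n_rw + 1) / params.rewarm_tau)
            + rng.normal(0, params.noise_sd, n_rw)
        )
        rows.append(
            {
                "nest_id": nest_id,
                "onset": start + s * one_min,
                "duration": dur,
                "true_class": "extended" if is_ext else "short",
                "t12_true": float(T12),
                "t6_true": float(T6),
                "body_condition": float(body_condition),
            }
        )
        t = e + params.refractory_min
    trace = TemperatureTrace(
        logger_id=f"L{nest_id}",
        nest_id=nest_id,
        site=ground.site,
        start=start,
        temps=temps,
    )
    truth = pd.DataFrame(
        rows,
        columns=[
            "nest_id", "onset", "duration", "true_class",
            "t12_true", "t6_true", "body_condition",
        ],
    )
    return trace, truth


def simulate_study(
    params: GeneratorParams | None = None, seed: int = 0
) -> StudyBundle:
    """Simulate the full input bundle: traces, ground, metadata, morphometrics.

    Deterministic in ``(params, seed)``.  Body condition is planted per
    nest and also encoded in the morphometrics (mass, tarsus) so that the
    scaled-mass-index computation can re-derive it.
    """
    params = params or GeneratorParams()
    root = np.random.SeedSequence(seed)
    ss = root.spawn(params.n_nests + 2)
    rng0 = np.random.default_rng(ss[0])
    ground = simulate_ground(
        params, n_days=params.days_per_nest + 1, seed=rng0
    )

    traces: list[TemperatureTrace] = []
    metadata: list[NestMetadata] = []
    morph: list[BirdMeasurement] = []
    bc_map: dict[str, float] = {}
    sex_map: dict[str, str] = {}
    truths = []
    rng_b = np.random.default_rng(ss[1])
    l0 = params.tarsus_mean
    for i in range(params.n_nests):
        nest_id = f"N{i:03d}"
        bc = float(rng_b.normal(params.bc_mean, params.bc_sd))
        tarsus = float(rng_b.normal(params.tarsus_mean, params.tarsus_sd))
        mass = float(np.clip(bc * (tarsus / l0) ** params.sma_exponent_true, 31.0, 89.0))
        sex = "F" if rng_b.uniform() < 0.5 else "M"
        trace, truth = simulate_nest(
            params, ground, bc, seed=np.random.default_rng(ss[2 + i]), nest_id=nest_id
        )
        traces.append(trace)
        truths.append(truth)
        bc_map[nest_id] = bc
        sex_map[nest_id] = sex
        metadata.append(
            NestMetadata(
                nest_id=nest_id,
                site=params.site,
                year=ground.start.year,
                incubation_start=(ground.start - pd.Timedelta(days=5)).date(),
                strategy="uniparental" if params.uniparental else "biparental",
                sex=sex,
            )
        )
        morph.append(
            BirdMeasurement(
                bird_id=f"B{i:03d}",
                nest_id=nest_id,
                mass=round(mass, 1),
                tarsus=round(tarsus, 2),
                sex=sex,
                capture_datetime=ground.start + pd.Timedelta(days=2),
            )
        )
    truth = (
        pd.concat(truths, ignore_index=True)
        if truths
        else pd.DataFrame(
            columns=[
                "nest_id", "onset", "duration", "true_class",
                "t12_true", "t6_true", "body_condition",
            ]
        )
    )
    return StudyBundle(
        params=params,
        seed=seed,
        ground=ground,
        traces=traces,
        metadata=metadata,
        morphometrics=morph,
        body_condition=bc_map,
        sex=sex_map,
        truth=truth,
    )


def simulate_recess_table(
    params: GeneratorParams | None = None,
    seed: int = 0,
    *,
    n_nests: int | None = None,
    n_days: int | None = None,
    windows: Sequence[int] = (1, 2, 6, 12, 24),
) -> pd.DataFrame:
    """Recess-level draw from the generator's statistical models only.

    Skips the minute-resolution thermal simulation (no traces, no
    detection): recess onsets come from the same hazard process, window
    covariates from one shared ground series, and the extended flag /
    durations from the occurrence and duration models.  This is the fast
    path for model-recovery experiments at scale.
    """
    params = params or GeneratorParams()
    n_nests = n_nests or params.n_nests
    n_days = n_days or params.days_per_nest
    root = np.random.SeedSequence(seed)
    ss = root.spawn(2)
    rng_g = np.random.default_rng(ss[0])
    rng = np.random.default_rng(ss[1])
    ground = simulate_ground(params, n_days=n_days + 1, seed=rng_g)
    g = ground.temps
    n = g.size
    roll = {h: _rolling_mean(g, h * 60) for h in windows}
    night = _night_mask(n, ground.start)
    hazard = np.where(
        night,
        params.day_hazard * params.night_rate_factor,
        params.day_hazard,
    )
    one_min = pd.Timedelta(minutes=1)
    frames = []
    for i in range(n_nests):
        nest_id = f"N{i:03d}"
        bc = rng.normal(params.bc_mean, params.bc_sd)
        u_occ = rng.normal(0, params.occ_nest_sd)
        u_dur = rng.normal(0, params.dur_nest_sd)
        sex = "F" if rng.uniform() < 0.5 else "M"
        cand = np.where(rng.uniform(size=n) < hazard)[0]
        cand = cand[cand >= 1440]
        r12 = roll[12] if 12 in roll else _rolling_mean(g, 720)
        r6 = roll[6] if 6 in roll else _rolling_mean(g, 360)
        onsets_l, ext_l, dur_l = [], [], []
        t_next = 0
        for s in cand:
            if s < t_next:  # bird still off nest (or refractory)
                continue
            T12, T6 = r12[s], r6[s]
            is_ext = rng.uniform() < expit(
                params.occ_beta0 + params.occ_betaT * T12 + u_occ
            )
            if is_ext:
                d = round(_extended_duration(params, T6, bc, u_dur, rng))
            else:
                d = max(
                    3.0,
                    round(
                        np.exp(
                            rng.normal(
                                params.short_dur_logmean, params.short_dur_logsd
                            )
                        )
                    ),
                )
            onsets_l.append(int(s))
            ext_l.append(is_ext)
            dur_l.append(float(d))
            t_next = s + int(d) + params.refractory_min
        onsets = np.array(onsets_l, dtype=int)
        ext = np.array(ext_l, dtype=bool)
        dur = np.array(dur_l, dtype=float)
        f = pd.DataFrame(
            {
                "nest_id": nest_id,
                "onset": [ground.start + int(s) * one_min for s in onsets],
                "duration": dur,
                "extended": ext.astype(int),
                "body_condition": bc,
                "sex": sex,
                "nest_type": "uni",
                "incubation_date": (onsets // 1440) + 5,
                "period": np.where(night[onsets], "night", "day"),
            }
        )
        for h in windows:
            f[f"t_mean_{h}h"] = roll[h][onsets]
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def expected_recesses_per_day(params: GeneratorParams, uniparental: bool = True) -> float:
    """Renewal-theory expectation of recesses per nest-day.

    Expected cycle = mean waiting time (1 / time-averaged hazard) + mean
    bout duration + refractory; recesses/day = 1440 / cycle.
    """
    h0 = params.day_hazard if uniparental else params.bi_day_hazard
    hbar = h0 * (480 + 960 * params.night_rate_factor) / 1440.0
    p_ext = (
        float(expit(params.occ_beta0 + params.occ_betaT * params.ground_mean))
        if uniparental
        else 0.0
    )
    e_short = float(np.exp(params.short_dur_logmean + params.short_dur_logsd**2 / 2))
    e_ext = float(np.exp(params.ext_dur_logmean + params.ext_dur_logsd**2 / 2))
    e_dur = (1 - p_ext) * e_short + p_ext * e_ext
    cycle = 1.0 / hbar + e_dur + params.refractory_min
    return 1440.0 / cycle
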