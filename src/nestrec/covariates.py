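"""Model covariates: body condition, pre-recess temperature windows, period.

Body condition is the scaled mass index (SMI): body mass standardized to a
reference tarsus length through the standardized-major-axis (SMA) scaling
exponent of ln(mass) on ln(tarsus).  Pre-recess micro-climate is the mean
ground-level temperature over a window of 1, 2, 6, 12 or 24 h ending at the
recess onset.  The day/night split follows the birds' incubation rhythm
under permanent Arctic daylight: "night" is 17:00-09:00 local time.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from nestrec.detection import Recess
from nestrec.timeseries_io import GroundSeries

WINDOW_HOURS = (1, 2, 6, 12, 24)
NIGHT_START_HOUR = 17
NIGHT_END_HOUR = 9

MASS_BAND_G = (30.0, 90.0)


@dataclass
class BirdMeasurement:
    """One capture record of an incubating bird."""

    bird_id: str
    nest_id: str
    mass: float  # g, spring scale +- 1 g
    tarsus: float  # mm, callipers +- 0.1 mm
    sex: str = "unknown"
    capture_datetime: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        if not (MASS_BAND_G[0] <= self.mass <= MASS_BAND_G[1]):
            raise ValueError(f"mass {self.mass} g outside plausible band {MASS_BAND_G}")
        if self.tarsus <= 0:
            raise ValueError("tarsus must be positive")


def sma_exponent(mass: np.ndarray, tarsus: np.ndarray) -> float:
    """Standardized-major-axis slope of ln(mass) on ln(tarsus).

    Equals the OLS slope divided by the Pearson correlation.  Needs at least
    3 birds and a nonzero correlation.
    """
    lm, lt = np.log(np.asarray(mass, float)), np.log(np.asarray(tarsus, float))
    if lm.size < 3:
        raise ValueError("need >= 3 birds to fit the SMA scaling exponent")
    res = stats.linregress(lt, lm)
    if not np.isfinite(res.rvalue) or res.rvalue == 0:
        raise ValueError("scaling exponent undefined: zero/undefined correlation")
    return float(res.slope / res.rvalue)


def scaled_mass_index(
    measurements: Sequence[BirdMeasurement],
    ref_length: float | str = "population mean",
) -> pd.DataFrame:
    """Scaled mass index per bird: SMI_i = mass_i * (L0 / tarsus_i) ** b_SMA.

    ``ref_length`` (L0, mm) defaults to the arithmetic mean tarsus of the
    sample; pass a number to reproduce a published L0.  Returns a DataFrame
    with bird_id, nest_id, mass, tarsus, sex and smi (grams).
    """
    mass = np.array([m.mass for m in measurements], float)
    tarsus = np.array([m.tarsus for m in measurements], float)
    b = sma_exponent(mass, tarsus)
    l0 = float(tarsus.mean()) if ref_length == "population mean" else float(ref_length)
    smi = mass * (l0 / tarsus) ** b
    return pd.DataFrame(
        {
            "bird_id": [m.bird_id for m in measurements],
            "nest_id": [m.nest_id for m in measurements],
            "mass": mass,
            "tarsus": tarsus,
            "sex": [m.sex for m in measurements],
            "smi": smi,
            "b_sma": b,
            "l0": l0,
        }
    )


def window_mean_ground_temp(
    gs: GroundSeries,
    t0: pd.Timestamp,
    hours: float,
    coverage_floor: float = 0.5,
) -> float:
    """Mean ground temperature over the half-open window [t0 - hours, t0).

    The mean uses covered minutes only; if coverage falls below
    ``coverage_floor`` the value is NaN (the recess is then dropped from
    models that use this window).
    """
    t0 = pd.Timestamp(t0)
    n = int(round(hours * 60))
    start = t0 - pd.Timedelta(minutes=n)
    i0 = int((start - gs.start) / pd.Timedelta(minutes=1))
    lo, hi = max(i0, 0), min(i0 + n, gs.temps.size)
    vals = gs.temps[lo:hi] if hi > lo else np.empty(0)
    vals = vals[np.isfinite(vals)]
    if vals.size < coverage_floor * n:
        return float("nan")
    return float(vals.mean())


def assign_period(onset: datetime | pd.Timestamp) -> str:
    """Day/night period of a recess onset (night = 17:00-09:00 local)."""
    h = pd.Timestamp(onset).hour
    return "night" if (h >= NIGHT_START_HOUR or h < NIGHT_END_HOUR) else "day"


def build_recess_covariates(
    recesses: Sequence[Recess],
    ground: GroundSeries,
    *,
    body_condition: dict[str, float] | None = None,
    sex: dict[str, str] | None = None,
    nest_type: dict[str, str] | None = None,
    incubation_start: dict[str, "datetime"] | None = None,
    windows: Sequence[float] = WINDOW_HOURS,
    coverage_floor: float = 0.5,
) -> pd.DataFrame:
    """One covariate row per recess, keyed by position in ``recesses``.

    Columns: nest_id, onset, duration, recess_class, extended (0/1),
    ``t_mean_{h}h`` for each window, body_condition, sex, nest_type,
    incubation_date (days since incubation start) and period (day/night).
    Per-nest dictionaries may be partial; missing keys yield NaN/None.
    """
    body_condition = body_condition or {}
    sex = sex or {}
    nest_type = nest_type or {}
    incubation_start = incubation_start or {}
    rows = []
    for i, r in enumerate(recesses):
        row: dict = {
            "recess_id": i,
            "nest_id": r.nest_id,
            "onset": r.onset,
            "duration": r.duration,
            "recess_class": r.recess_class,
            "extended": 1 if r.recess_class == "extended" else 0,
            "period": assign_period(r.onset),
            "body_condition": body_condition.get(r.nest_id, np.nan),
            "sex": sex.get(r.nest_id, "unknown"),
            "nest_type": nest_type.get(r.nest_id, "uni"),
        }
        start = incubation_start.get(r.nest_id)
        row["incubation_date"] = (
            (r.onset.normalize() - pd.Timestamp(start).normalize()).days
            if start is not None
            else np.nan
        )
        for h in windows:
            row[f"t_mean_{int(h)}h"] = window_mean_ground_temp(
                ground, r.onset, h, coverage_floor
            )
        rows.append(row)
    return pd.DataFrame(rows)
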