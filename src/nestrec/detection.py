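"""Segmentation of nest traces into incubation and recess bouts.

A recess is a maximal run of minutes during which the nest temperature sits
strictly below a per-day threshold:

* ``max_drop`` (primary): daily maximum nest temperature minus 4.5 degC, on
  the local calendar day of the run's onset;
* ``median_drop`` (legacy, for comparison): daily median minus 3.0 degC,
  scored only on days whose median exceeds a 36 degC quality floor.  The
  legacy rule breaks down for extended recesses because long off-bouts drag
  the daily median itself below the floor.

Runs shorter than ``min_duration`` (default 3 min, the onset/ending timing
uncertainty) are discarded.  Runs crossing midnight are evaluated against
the onset day's threshold and kept as a single recess; gap minutes always
terminate a run.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from nestrec.timeseries_io import TemperatureTrace

MAX_DROP = "max_drop"
MEDIAN_DROP = "median_drop"

#: offset between incubated-nest and ground-level temperature used to carry
#: the 36 degC incubation-quality floor over to a 37.5 degC daily-max floor
NEST_GROUND_OFFSET_C = 1.5


@dataclass
class DetectionParams:
    """Thresholds and quality floors for recess detection.

    All temperatures in degC, durations in minutes unless stated.
    """

    delta_max_drop: float = 4.5  # required drop below the daily max
    delta_median_drop: float = 3.0  # legacy: drop below the daily median
    min_duration: int = 3  # shortest scoreable recess
    median_quality_floor: float = 36.0  # legacy per-day quality rule
    daily_max_floor: float = 37.5  # daily-max quality rule (36 + offset)
    min_monitoring_hours: float = 24.0  # nest-level inclusion rule
    apply_max_floor_to: str = "nest"  # "nest" or "ground" reference

    def __post_init__(self) -> None:
        if self.min_duration < 1:
            raise ValueError("min_duration must be >= 1 minute")
        for name in ("delta_max_drop", "delta_median_drop",
                     "median_quality_floor", "daily_max_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Recess:
    """One detected off-nest bout.

    ``end`` is exclusive (first minute back at incubation temperature), so
    ``duration == (end - onset)`` in whole minutes.
    """

    nest_id: str
    onset: pd.Timestamp
    end: pd.Timestamp
    duration: int
    method: str = MAX_DROP
    is_capture_artifact: bool = False
    recess_class: str | None = None  # "short" | "extended", set later

    @property
    def day_of_onset(self) -> date:
        return self.onset.date()


@dataclass
class NestDay:
    """Per-nest per-calendar-day summary."""

    nest_id: str
    date: date
    tdr: float  # total daily duration of recesses, minutes
    n_recesses: int
    daily_max_temp: float
    daily_median_temp: float
    n_extended: int | None = None
    quality_pass: bool = True
    excluded_reason: str | None = None


def _daily_stat(trace: TemperatureTrace, stat: str) -> dict[date, float]:
    s = trace.to_series()
    grouped = s.groupby(s.index.date)
    agg = grouped.max() if stat == "max" else grouped.median()
    return {d: float(v) for d, v in agg.items() if np.isfinite(v)}


def detect_recesses(
    trace: TemperatureTrace,
    params: DetectionParams | None = None,
    method: str = MAX_DROP,
) -> list[Recess]:
    """Detect recesses in one nest trace.

    Returns an empty list (nest flagged by the quality filter later) when
    the trace has less coverage than ``min_monitoring_hours``.
    """
    params = params or DetectionParams()
    if method not in (MAX_DROP, MEDIAN_DROP):
        raise ValueError(f"unknown method {method!r}")
    if trace.monitored_hours < params.min_monitoring_hours:
        return []

    temps = trace.temps
    n = temps.size
    ts = trace.timestamps
    day_of = ts.normalize()

    if method == MAX_DROP:
        stats = _daily_stat(trace, "max")
        delta = params.delta_max_drop
        valid = stats
    else:
        stats = _daily_stat(trace, "median")
        delta = params.delta_median_drop
        # legacy method only scores days with an acceptable median
        valid = {d: m for d, m in stats.items() if m > params.median_quality_floor}

    thr_by_day = {d: m - delta for d, m in valid.items()}
    thr_own = np.array(
        [thr_by_day.get(d.date(), np.nan) for d in day_of], dtype=float
    )

    finite = np.isfinite(temps)
    below_own = finite & np.isfinite(thr_own) & (temps < thr_own)

    recesses: list[Recess] = []
    # vectorized candidate starts; the per-recess while-loop only walks
    # actual recess minutes, so cost is O(total recess minutes)
    starts = np.where(below_own & ~np.roll(below_own, 1))[0]
    if below_own.size and below_own[0]:
        starts = np.union1d(starts, [0])
    pos = 0
    one_min = pd.Timedelta(minutes=1)
    for s in starts:
        if s < pos:
            continue  # swallowed by a run that crossed midnight
        onset_thr = thr_own[s]
        j = s
        while j < n and finite[j] and temps[j] < onset_thr:
            j += 1
        pos = j
        dur = j - s
        if dur >= params.min_duration:
            recesses.append(
                Recess(
                    nest_id=trace.nest_id or trace.logger_id,
                    onset=ts[s],
                    end=ts[s] + dur * one_min,
                    duration=int(dur),
                    method=method,
                )
            )
    return recesses


def compute_tdr(recesses: Iterable[Recess], day: date) -> float:
    """Total daily duration of recesses: minutes of recess overlapping ``day``.

    Recesses crossing midnight contribute only the portion inside the day,
    so the per-nest sum of daily TDRs equals total recess minutes exactly.
    """
    d0 = pd.Timestamp(day)
    d1 = d0 + pd.Timedelta(days=1)
    total = 0.0
    for r in recesses:
        lo = max(r.onset, d0)
        hi = min(r.end, d1)
        if hi > lo:
            total += (hi - lo) / pd.Timedelta(minutes=1)
    return float(total)


def build_nest_days(
    trace: TemperatureTrace,
    recesses: Sequence[Recess],
    params: DetectionParams | None = None,
) -> list[NestDay]:
    """Per-day summaries (TDR, counts, daily temperature stats) for one nest."""
    params = params or DetectionParams()
    maxes = _daily_stat(trace, "max")
    medians = _daily_stat(trace, "median")
    nest_id = trace.nest_id or trace.logger_id
    live = [r for r in recesses if not r.is_capture_artifact]
    out = []
    for day in trace.days():
        n_on = sum(1 for r in live if r.day_of_onset == day)
        out.append(
            NestDay(
                nest_id=nest_id,
                date=day,
                tdr=compute_tdr(live, day),
                n_recesses=n_on,
                daily_max_temp=maxes.get(day, float("nan")),
                daily_median_temp=medians.get(day, float("nan")),
            )
        )
    return out


def flag_captures(
    recesses: Sequence[Recess],
    capture_events: Sequence[tuple[str, pd.Timestamp]],
) -> list[Recess]:
    """Mark recesses overlapping a recorded capture of the tending bird."""
    out = []
    for r in recesses:
        hit = any(
            nest == r.nest_id and r.onset <= pd.Timestamp(when) < r.end
            for nest, when in capture_events
        )
        out.append(replace(r, is_capture_artifact=hit) if hit else r)
    return out


def apply_quality_filters(
    nest_days: Sequence[NestDay],
    params: DetectionParams | None = None,
    *,
    monitored_hours: dict[str, float] | None = None,
    manual_exclusions: Sequence[tuple[str, date]] = (),
    method: str = MAX_DROP,
    ground_daily_max: dict[date, float] | None = None,
) -> tuple[list[NestDay], pd.DataFrame]:
    """Apply the record-quality rules; every exclusion carries a reason code.

    Rules: nests monitored under ``min_monitoring_hours``
    (``short_monitoring``); days whose daily max falls below
    ``daily_max_floor`` under the max-drop method (``daily_max_below_floor``)
    or whose median falls below ``median_quality_floor`` under the legacy
    method (``median_below_floor``); days on the manual erratic-pattern list
    (``manual_erratic``).  With ``params.apply_max_floor_to == "ground"``
    the daily-max rule is evaluated against ``ground_daily_max`` (per-day
    site reference maxima) instead of the nest trace.

    Returns the retained days and an exclusion report (one row per nest-day
    with its reason).
    """
    params = params or DetectionParams()
    manual = {(n, d) for n, d in manual_exclusions}
    kept: list[NestDay] = []
    excluded: list[dict] = []
    for nd in nest_days:
        reason = None
        if (
            monitored_hours is not None
            and monitored_hours.get(nd.nest_id, np.inf) < params.min_monitoring_hours
        ):
            reason = "short_monitoring"
        elif (nd.nest_id, nd.date) in manual:
            reason = "manual_erratic"
        elif method == MAX_DROP:
            if params.apply_max_floor_to == "ground" and ground_daily_max is not None:
                ref = ground_daily_max.get(nd.date, float("nan"))
            else:
                ref = nd.daily_max_temp
            if not (np.isfinite(ref) and ref >= params.daily_max_floor):
                reason = "daily_max_below_floor"
        elif method == MEDIAN_DROP and not (
            np.isfinite(nd.daily_median_temp)
            and nd.daily_median_temp > params.median_quality_floor
        ):
            reason = "median_below_floor"
        if reason is None:
            kept.append(nd)
        else:
            nd.quality_pass = False
            nd.excluded_reason = reason
            excluded.append(
                {"nest_id": nd.nest_id, "date": nd.date, "reason": reason}
            )
    report = pd.DataFrame(excluded, columns=["nest_id", "date", "reason"])
    return kept, report


def recesses_to_frame(recesses: Sequence[Recess]) -> pd.DataFrame:
    """Tabular view of a recess list (one row per recess)."""
    return pd.DataFrame(
        {
            "nest_id": [r.nest_id for r in recesses],
            "onset": [r.onset for r in recesses],
            "end": [r.end for r in recesses],
            "duration": [r.duration for r in recesses],
            "method": [r.method for r in recesses],
            "day_of_onset": [r.day_of_onset for r in recesses],
            "is_capture_artifact": [r.is_capture_artifact for r in recesses],
            "recess_class": [r.recess_class for r in recesses],
        }
    )


def compare_methods(
    trace: TemperatureTrace, params: DetectionParams | None = None
) -> pd.DataFrame:
    """Run both detection rules on one trace and match their recesses.

    Recesses are matched greedily by interval-overlap (Jaccard) fraction.
    Columns: onset/duration under each method (NaT/NaN when unmatched) and
    ``overlap_frac``; one row per recess found by either method.
    """
    params = params or DetectionParams()
    a = detect_recesses(trace, params, MAX_DROP)
    b = detect_recesses(trace, params, MEDIAN_DROP)

    def overlap(r1: Recess, r2: Recess) -> float:
        lo = max(r1.onset, r2.onset)
        hi = min(r1.end, r2.end)
        inter = max((hi - lo) / pd.Timedelta(minutes=1), 0.0)
        union = r1.duration + r2.duration - inter
        return inter / union if union > 0 else 0.0

    pairs = sorted(
        (
            (overlap(r1, r2), i, j)
            for i, r1 in enumerate(a)
            for j, r2 in enumerate(b)
            if overlap(r1, r2) > 0
        ),
        reverse=True,
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    rows = []
    for frac, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        rows.append(
            {
                "onset_max_drop": a[i].onset,
                "duration_max_drop": a[i].duration,
                "onset_median_drop": b[j].onset,
                "duration_median_drop": b[j].duration,
                "overlap_frac": frac,
                "matched": True,
            }
        )
    for i, r in enumerate(a):
        if i not in used_a:
            rows.append(
                {
                    "onset_max_drop": r.onset,
                    "duration_max_drop": r.duration,
                    "onset_median_drop": pd.NaT,
                    "duration_median_drop": np.nan,
                    "overlap_frac": 0.0,
                    "matched": False,
                }
            )
    for j, r in enumerate(b):
        if j not in used_b:
            rows.append(
                {
                    "onset_max_drop": pd.NaT,
                    "duration_max_drop": np.nan,
                    "onset_median_drop": r.onset,
                    "duration_median_drop": r.duration,
                    "overlap_frac": 0.0,
                    "matched": False,
                }
            )
    cols = [
        "onset_max_drop",
        "duration_max_drop",
        "onset_median_drop",
        "duration_median_drop",
        "overlap_frac",
        "matched",
    ]
    return pd.DataFrame(rows, columns=cols)
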