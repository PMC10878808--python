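"""Reading, validation and regularization of thermologger time series.

Loggers record nest (or bare-ground) temperature once per minute.  All
downstream computation assumes a regular 1-minute grid, so traces are
re-indexed onto that grid on ingest: missing minutes become explicit gaps
(NaN) and are never interpolated.  Timestamps are timezone-naive local time;
the "day" used everywhere is the local calendar date.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical CSV dialect used by :func:`read_logger_csv` / :func:`write_logger_csv`.
CANONICAL_DIALECT: dict = {
    "timestamp_col": "timestamp",
    "temp_col": "temp_c",
    "datetime_format": "ISO8601",
    "decimal": ".",
}

#: Preset for CSV exports of TinyTag logger software (header row, comma
#: separated, "dd/mm/yyyy HH:MM:SS" timestamps).
TINYTAG_DIALECT: dict = {
    "timestamp_col": "Time",
    "temp_col": "Temperature",
    "datetime_format": "%d/%m/%Y %H:%M:%S",
    "decimal": ".",
}

PLAUSIBILITY_BAND = (-40.0, 60.0)


class LoggerFileError(RuntimeError):
    """Raised when a logger file cannot be ingested."""


@dataclass
class TemperatureTrace:
    """A per-logger temperature series on a regular 1-minute grid.

    Parameters
    ----------
    logger_id, nest_id, site
        Identifiers.  ``nest_id`` is ``None`` for bare-ground loggers.
    start
        Timestamp of the first minute (timezone-naive local time).
    temps
        One value per minute from ``start``; NaN marks a gap.
    """

    logger_id: str
    nest_id: str | None
    site: str
    start: pd.Timestamp
    temps: np.ndarray
    gaps: list[tuple[pd.Timestamp, pd.Timestamp]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start).floor("min")
        self.temps = np.asarray(self.temps, dtype=float)
        if self.temps.ndim != 1 or self.temps.size == 0:
            raise ValueError("temps must be a non-empty 1-d array")
        if not self.gaps:
            self.gaps = _gaps_from_nan(self.start, self.temps)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=self.temps.size, freq="min")

    @property
    def n_minutes(self) -> int:
        return int(self.temps.size)

    @property
    def end(self) -> pd.Timestamp:
        """Timestamp of the last minute (inclusive)."""
        return self.start + pd.Timedelta(minutes=self.temps.size - 1)

    @property
    def monitored_hours(self) -> float:
        """Hours of non-gap coverage."""
        return float(np.isfinite(self.temps).sum()) / 60.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"timestamp": self.timestamps, "temp_c": self.temps}
        )

    def to_series(self) -> pd.Series:
        return pd.Series(self.temps, index=self.timestamps, name="temp_c")

    def day_slice(self, day: date) -> np.ndarray:
        """Temperatures for one local calendar day (may contain NaN)."""
        ts = self.timestamps
        mask = (ts.date >= day) & (ts.date <= day)
        return self.temps[mask]

    def days(self) -> list[date]:
        """Calendar days with at least one covered minute."""
        ts = self.timestamps[np.isfinite(self.temps)]
        return sorted(set(ts.date))


@dataclass
class NestMetadata:
    """Static per-nest information from the field database."""

    nest_id: str
    site: str
    year: int
    incubation_start: date
    strategy: str  # uniparental | biparental | swap
    sex: str = "unknown"  # M | F | unknown
    monitoring_start: pd.Timestamp | None = None
    monitoring_end: pd.Timestamp | None = None

    STRATEGIES = ("uniparental", "biparental", "swap")

    def __post_init__(self) -> None:
        if self.strategy not in self.STRATEGIES:
            raise ValueError(
                f"strategy must be one of {self.STRATEGIES}, got {self.strategy!r}"
            )
        self.incubation_start = pd.Timestamp(self.incubation_start).date()


@dataclass
class GroundSeries:
    """Site-level ground temperature reference on a 1-minute grid.

    Built from loggers in inactive nests (deserted, depredated or hatched),
    which sample the breeding microhabitat at ground level.
    """

    site: str
    start: pd.Timestamp
    temps: np.ndarray

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start).floor("min")
        self.temps = np.asarray(self.temps, dtype=float)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=self.temps.size, freq="min")

    def to_series(self) -> pd.Series:
        return pd.Series(self.temps, index=self.timestamps, name="ground_c")


def _gaps_from_nan(
    start: pd.Timestamp, temps: np.ndarray
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """(first, last) missing minute of every NaN run."""
    isnan = ~np.isfinite(temps)
    if not isnan.any():
        return []
    edges = np.diff(isnan.astype(int))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0])
    if isnan[0]:
        starts.insert(0, 0)
    if isnan[-1]:
        ends.append(temps.size - 1)
    one_min = pd.Timedelta(minutes=1)
    return [(start + s * one_min, start + e * one_min) for s, e in zip(starts, ends)]


def read_logger_csv(
    path: str | Path,
    dialect: dict | None = None,
    *,
    logger_id: str | None = None,
    nest_id: str | None = None,
    site: str = "",
    plausibility_band: tuple[float, float] = PLAUSIBILITY_BAND,
) -> TemperatureTrace:
    """Read one logger export and return a validated, regularized trace.

    Rows that fail datetime/number parsing or fall outside the plausibility
    band are dropped (and logged); duplicated timestamps collapse to the
    first occurrence; the result is re-indexed onto a full 1-minute grid
    with explicit NaN gaps.

    Raises
    ------
    LoggerFileError
        If the file is unreadable, lacks the dialect's columns, or more than
        half of its rows are unusable.
    """
    path = Path(path)
    d = dict(CANONICAL_DIALECT if dialect is None else dialect)
    try:
        raw = pd.read_csv(
            path, decimal=d.get("decimal", "."), float_precision="round_trip"
        )
    except Exception as exc:  # noqa: BLE001 - any parse failure is terminal
        raise LoggerFileError(f"cannot read {path}: {exc}") from exc
    for col in (d["timestamp_col"], d["temp_col"]):
        if col not in raw.columns:
            raise LoggerFileError(f"{path}: missing column {col!r}")

    n_in = len(raw)
    if n_in == 0:
        raise LoggerFileError(f"{path}: empty file")
    fmt = d.get("datetime_format", "ISO8601")
    ts = pd.to_datetime(raw[d["timestamp_col"]], format=fmt, errors="coerce")
    temp = pd.to_numeric(raw[d["temp_col"]], errors="coerce")
    lo, hi = plausibility_band
    ok = ts.notna() & temp.notna() & (temp >= lo) & (temp <= hi)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%s: dropped %d unparseable/implausible rows", path, n_bad)
    if n_bad > 0.5 * n_in:
        raise LoggerFileError(f"{path}: {n_bad}/{n_in} rows unusable")

    frame = pd.DataFrame({"ts": ts[ok].dt.floor("min"), "temp": temp[ok]})
    n_dup = int(frame["ts"].duplicated().sum())
    if n_dup:
        logger.warning("%s: collapsed %d duplicated timestamps to first", path, n_dup)
    frame = frame.drop_duplicates("ts", keep="first").sort_values("ts")

    grid = pd.date_range(frame["ts"].iloc[0], frame["ts"].iloc[-1], freq="min")
    temps = frame.set_index("ts")["temp"].reindex(grid).to_numpy()
    return TemperatureTrace(
        logger_id=logger_id or path.stem,
        nest_id=nest_id,
        site=site,
        start=grid[0],
        temps=temps,
    )


def write_logger_csv(trace: TemperatureTrace, path: str | Path) -> None:
    """Write a trace in the canonical dialect (gap minutes are omitted)."""
    frame = trace.to_frame()
    frame = frame[np.isfinite(frame["temp_c"])]
    frame["timestamp"] = frame["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    # str() round-trips doubles exactly; avoid float_format truncation
    frame["temp_c"] = [repr(float(v)) for v in frame["temp_c"]]
    frame.to_csv(path, index=False)


def build_ground_series(
    traces: Sequence[TemperatureTrace], site: str
) -> GroundSeries:
    """Combine inactive-nest loggers into one site-level reference series.

    The default combination rule is the per-minute mean across whichever
    loggers cover that minute; minutes covered by no logger are gaps.
    """
    traces = [t for t in traces if t.site == site or not t.site]
    if not traces:
        raise ValueError(f"no inactive-nest traces for site {site!r}")
    start = min(t.start for t in traces)
    end = max(t.end for t in traces)
    n = int((end - start) / pd.Timedelta(minutes=1)) + 1
    acc = np.zeros(n)
    cnt = np.zeros(n)
    for t in traces:
        off = int((t.start - start) / pd.Timedelta(minutes=1))
        fin = np.isfinite(t.temps)
        acc[off : off + t.temps.size][fin] += t.temps[fin]
        cnt[off : off + t.temps.size][fin] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return GroundSeries(site=site, start=start, temps=mean)


def daily_ground_stats(gs: GroundSeries, day: date) -> dict:
    """Mean and max ground temperature over the covered minutes of one day.

    Returns ``{"mean": nan, "max": nan, "coverage": 0.0}`` (flagged missing)
    when the day has no coverage.
    """
    mask = gs.timestamps.date == day
    vals = gs.temps[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return {"mean": float("nan"), "max": float("nan"), "coverage": 0.0}
    return {
        "mean": float(vals.mean()),
        "max": float(vals.max()),
        "coverage": float(vals.size / 1440.0),
    }


def read_nest_metadata(path: str | Path) -> list[NestMetadata]:
    """Read the nest metadata table (CSV with documented column schema)."""
    raw = pd.read_csv(path)
    out = []
    for _, row in raw.iterrows():
        out.append(
            NestMetadata(
                nest_id=str(row["nest_id"]),
                site=str(row["site"]),
                year=int(row["year"]),
                incubation_start=pd.Timestamp(row["incubation_start"]).date(),
                strategy=str(row["strategy"]),
                sex=str(row.get("sex", "unknown")),
            )
        )
    return out
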