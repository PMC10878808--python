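"""Recess segmentation: threshold rule, TDR bookkeeping, quality filters."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nestrec.detection import (
    MAX_DROP,
    MEDIAN_DROP,
    DetectionParams,
    Recess,
    apply_quality_filters,
    build_nest_days,
    compare_methods,
    compute_tdr,
    detect_recesses,
    flag_captures,
)
from nestrec.timeseries_io import TemperatureTrace

START = pd.Timestamp("2019-06-20 00:00")


def make_trace(temps, nest_id="N1"):
    return TemperatureTrace(
        logger_id="L1", nest_id=nest_id, site="SYN", start=START,
        temps=np.asarray(temps, float),
    )


def brute_force_detect(trace, params, method=MAX_DROP):
    """Independent per-minute scan: maximal runs strictly below the
    onset-day threshold, >= min_duration, terminated by gaps."""
    temps = trace.temps
    ts = trace.timestamps
    stat = {}
    for day in set(ts.date):
        vals = temps[(ts.date == day) & np.isfinite(temps)]
        if vals.size == 0:
            continue
        m = np.max(vals) if method == MAX_DROP else np.median(vals)
        if method == MEDIAN_DROP and m <= params.median_quality_floor:
            continue
        stat[day] = m - (
            params.delta_max_drop if method == MAX_DROP else params.delta_median_drop
        )
    found = []
    i = 0
    n = temps.size
    while i < n:
        day = ts[i].date()
        if (
            day in stat
            and np.isfinite(temps[i])
            and temps[i] < stat[day]
        ):
            thr = stat[day]
            j = i
            while j < n and np.isfinite(temps[j]) and temps[j] < thr:
                j += 1
            if j - i >= params.min_duration:
                found.append((i, j - i))
            i = j
        else:
            i += 1
    return found


class TestDetectRecesses:
    def test_clear_dip(self):
        temps = np.full(2880, 38.0)
        temps[600:610] = 30.0
        rec = detect_recesses(make_trace(temps))
        assert len(rec) == 1
        assert rec[0].onset == START + pd.Timedelta(minutes=600)
        assert rec[0].duration == 10

    def test_shallow_dip_below_required_drop(self):
        temps = np.full(2880, 38.0)
        temps[600:610] = 34.0  # drop of 4.0 < 4.5
        assert detect_recesses(make_trace(temps)) == []

    def test_too_short_dip(self):
        temps = np.full(2880, 38.0)
        temps[600:602] = 30.0  # 2 min < 3-min minimum
        assert detect_recesses(make_trace(temps)) == []

    def test_exactly_at_threshold_is_incubation(self):
        temps = np.full(2880, 38.0)
        temps[600:610] = 38.0 - 4.5  # not strictly below
        assert detect_recesses(make_trace(temps)) == []

    def test_midnight_crossing_uses_onset_day_threshold(self):
        temps = np.full(2880, 38.0)
        temps[1380:1500] = 30.0  # 23:00 -> 01:00
        rec = detect_recesses(make_trace(temps))
        assert len(rec) == 1
        assert rec[0].duration == 120

    def test_gap_terminates_run(self):
        temps = np.full(2880, 38.0)
        temps[600:640] = 30.0
        temps[615:620] = np.nan
        rec = detect_recesses(make_trace(temps))
        assert [r.duration for r in rec] == [15, 20]

    def test_short_monitoring_gives_empty(self):
        temps = np.full(600, 38.0)  # 10 h < 24 h
        temps[100:120] = 30.0
        assert detect_recesses(make_trace(temps)) == []

    def test_planted_short_and_extended_recovered(self, small_bundle):
        trace = small_bundle.traces[0]
        truth = small_bundle.truth[small_bundle.truth.nest_id == trace.nest_id]
        rec = detect_recesses(trace)
        assert len(rec) == len(truth)
        for r, (_, t) in zip(rec, truth.iterrows()):
            assert abs((r.onset - t.onset) / pd.Timedelta(minutes=1)) <= 1
            assert abs(r.duration - t.duration) <= 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_random_days(self, seed):
        rng = np.random.default_rng(seed)
        temps = 38.0 + rng.normal(0, 0.3, 1440 * 2)
        for _ in range(rng.integers(2, 8)):
            s = int(rng.integers(0, 2700))
            d = int(rng.integers(1, 60))
            temps[s : s + d] -= rng.uniform(2.0, 15.0)
        if seed % 2:
            g = int(rng.integers(0, 2800))
            temps[g : g + 30] = np.nan
        trace = make_trace(temps)
        params = DetectionParams()
        got = [
            (int((r.onset - START) / pd.Timedelta(minutes=1)), r.duration)
            for r in detect_recesses(trace, params)
        ]
        assert got == brute_force_detect(trace, params)

    def test_monotone_in_required_drop(self):
        rng = np.random.default_rng(3)
        temps = 38.0 + rng.normal(0, 0.3, 2880)
        for s in (200, 700, 1600, 2100):
            temps[s : s + 20] -= rng.uniform(3, 12)
        trace = make_trace(temps)
        counts = [
            len(detect_recesses(trace, DetectionParams(delta_max_drop=d)))
            for d in (3.0, 4.5, 6.0, 9.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestTdr:
    def _rec(self, onset_min, dur):
        onset = START + pd.Timedelta(minutes=onset_min)
        return Recess(
            nest_id="N1", onset=onset,
            end=onset + pd.Timedelta(minutes=dur), duration=dur,
        )

    def test_simple_sum(self):
        recs = [self._rec(100, 10), self._rec(300, 20), self._rec(600, 30)]
        assert compute_tdr(recs, START.date()) == 60

    def test_midnight_split(self):
        recs = [self._rec(23 * 60 + 30, 100)]  # 23:30, 100 min
        assert compute_tdr(recs, START.date()) == 30
        assert compute_tdr(recs, (START + pd.Timedelta(days=1)).date()) == 70

    def test_empty(self):
        assert compute_tdr([], START.date()) == 0.0

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 4300), st.integers(3, 500)),
            min_size=0,
            max_size=12,
        )
    )
    def test_split_conserves_total_minutes(self, bouts):
        """However recesses straddle midnight, day-portions sum exactly."""
        recs = [self._rec(onset, dur) for onset, dur in bouts]
        days = pd.date_range(START, periods=5, freq="D")
        total = sum(compute_tdr(recs, d.date()) for d in days)
        assert total == sum(dur for _, dur in bouts)

    def test_conservation_over_days(self, small_bundle):
        for trace in small_bundle.traces[:3]:
            recs = detect_recesses(trace)
            total = sum(r.duration for r in recs)
            days = pd.date_range(
                trace.start.normalize(), trace.end.normalize(), freq="D"
            )
            assert sum(compute_tdr(recs, d.date()) for d in days) == total


class TestQualityFilters:
    def _day(self, nest="N1", d=date(2019, 6, 20), dmax=39.0, dmed=38.0):
        from nestrec.detection import NestDay

        return NestDay(
            nest_id=nest, date=d, tdr=100.0, n_recesses=5,
            daily_max_temp=dmax, daily_median_temp=dmed,
        )

    def test_daily_max_below_floor(self):
        kept, report = apply_quality_filters([self._day(dmax=36.0)])
        assert kept == []
        assert report.iloc[0]["reason"] == "daily_max_below_floor"

    def test_short_monitoring(self):
        kept, report = apply_quality_filters(
            [self._day()], monitored_hours={"N1": 23.0}
        )
        assert kept == []
        assert report.iloc[0]["reason"] == "short_monitoring"

    def test_manual_exclusion(self):
        kept, report = apply_quality_filters(
            [self._day()], manual_exclusions=[("N1", date(2019, 6, 20))]
        )
        assert kept == []
        assert report.iloc[0]["reason"] == "manual_erratic"

    def test_median_floor_applies_to_legacy_method(self):
        kept, report = apply_quality_filters(
            [self._day(dmed=35.0)], method=MEDIAN_DROP
        )
        assert kept == []
        assert report.iloc[0]["reason"] == "median_below_floor"

    def test_passing_day_retained_with_no_reason(self):
        kept, report = apply_quality_filters([self._day()])
        assert len(kept) == 1 and kept[0].quality_pass
        assert report.empty

    def test_capture_flagging(self):
        onset = START + pd.Timedelta(minutes=100)
        r = Recess("N1", onset, onset + pd.Timedelta(minutes=30), 30)
        flagged = flag_captures([r], [("N1", onset + pd.Timedelta(minutes=5))])
        assert flagged[0].is_capture_artifact
        unflagged = flag_captures([r], [("N2", onset)])
        assert not unflagged[0].is_capture_artifact


class TestCompareMethods:
    def test_clean_short_dips_fully_matched(self):
        rng = np.random.default_rng(5)
        temps = 38.0 + rng.normal(0, 0.1, 2880)
        for s in (200, 700, 1600, 2100):
            temps[s : s + 15] = 25.0  # deep, below both thresholds
        tab = compare_methods(make_trace(temps))
        assert len(tab) == 4
        assert tab["matched"].all()
        assert (tab["overlap_frac"] > 0.9).all()

    def test_long_extended_recess_breaks_median_method(self):
        # 800 low minutes drag the daily median below the 36 degC quality
        # floor: the legacy method scores nothing, max-drop still works
        rng = np.random.default_rng(6)
        temps = 38.0 + rng.normal(0, 0.1, 2880)
        temps[200:1000] = 10.0
        trace = make_trace(temps)
        assert len(detect_recesses(trace, method=MAX_DROP)) == 1
        day1 = [
            r
            for r in detect_recesses(trace, method=MEDIAN_DROP)
            if r.day_of_onset == START.date()
        ]
        assert day1 == []
        tab = compare_methods(trace)
        long_row = tab[tab["duration_max_drop"] == 800]
        assert not long_row.empty and not long_row.iloc[0]["matched"]

    def test_empty_day(self):
        tab = compare_methods(make_trace(np.full(2880, 38.0)))
        assert tab.empty


class TestNestDays:
    def test_counts_and_stats(self):
        temps = np.full(2880, 38.0)
        temps[100:110] = 30.0
        temps[1500:1520] = 30.0
        trace = make_trace(temps)
        recs = detect_recesses(trace)
        days = build_nest_days(trace, recs)
        assert len(days) == 2
        assert days[0].n_recesses == 1 and days[0].tdr == 10
        assert days[1].n_recesses == 1 and days[1].tdr == 20
        assert days[0].daily_max_temp == pytest.approx(38.0)
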