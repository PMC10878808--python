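"""Antimode threshold estimation, bootstrap CI and strategy assignment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nestrec.classification import (
    AntimodeError,
    StrategyDiscriminant,
    assign_strategy,
    bootstrap_by_stratum,
    bootstrap_threshold,
    classify_recesses,
    estimate_antimode,
)
from nestrec.detection import Recess

START = pd.Timestamp("2019-06-20 00:00")


def lognormal_mixture(rng, n, w_ext=0.5, mu1=np.log(7), s1=0.7, mu2=np.log(340), s2=0.45):
    n2 = int(round(n * w_ext))
    return np.exp(
        np.concatenate([rng.normal(mu1, s1, n - n2), rng.normal(mu2, s2, n2)])
    )


def grid_oracle_antimode(durations, bandwidth, step=0.01):
    """Independent direct-sum Gaussian KDE on a fine log grid; the minimum
    between the two highest local maxima."""
    x = np.log(durations)
    grid = np.arange(x.min() - 3 * bandwidth, x.max() + 3 * bandwidth, step)
    dens = np.exp(
        -0.5 * ((grid[:, None] - x[None, :]) / bandwidth) ** 2
    ).sum(axis=1) / (x.size * bandwidth * np.sqrt(2 * np.pi))
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.where(interior)[0] + 1
    top2 = sorted(peaks[np.argsort(dens[peaks])[-2:]])
    lo, hi = top2
    return float(np.exp(grid[lo + np.argmin(dens[lo : hi + 1])]))


class TestEstimateAntimode:
    def test_matches_grid_oracle_on_mixture(self):
        rng = np.random.default_rng(42)
        d = lognormal_mixture(rng, 5000)
        est = estimate_antimode(d)
        oracle = grid_oracle_antimode(d, est.bandwidth)
        assert est.antimode == pytest.approx(oracle, rel=0.10)
        assert est.modes[0] < est.antimode < est.modes[1]
        assert est.modes[0] == pytest.approx(7.0, rel=0.35)
        assert est.modes[1] == pytest.approx(340.0, rel=0.35)

    def test_identical_durations_error(self):
        with pytest.raises(AntimodeError):
            estimate_antimode(np.full(100, 10.0))

    def test_too_few_durations_error(self):
        with pytest.raises(AntimodeError, match="need >="):
            estimate_antimode(np.arange(1, 20))

    def test_scale_consistency_under_rescaling(self):
        # multiplying all durations by c multiplies the log-scale antimode
        rng = np.random.default_rng(7)
        d = lognormal_mixture(rng, 3000)
        e1 = estimate_antimode(d)
        e2 = estimate_antimode(3.0 * d, bandwidth=e1.bandwidth)
        assert e2.antimode == pytest.approx(3.0 * e1.antimode, rel=0.02)
        # label partition is preserved relative to the scaled threshold
        assert np.array_equal(d >= e1.antimode, 3.0 * d >= e2.antimode)


class TestBootstrapThreshold:
    def test_reproducible_with_seed(self):
        rng = np.random.default_rng(1)
        d = lognormal_mixture(rng, 1000)
        a = bootstrap_threshold(d, n_boot=50, seed=9)
        b = bootstrap_threshold(d, n_boot=50, seed=9)
        assert (a.antimode, a.ci_low, a.ci_high) == (b.antimode, b.ci_low, b.ci_high)
        assert a.ci_low <= a.antimode <= a.ci_high

    def test_single_resample_degenerate_ci(self):
        rng = np.random.default_rng(2)
        d = lognormal_mixture(rng, 1000)
        est = bootstrap_threshold(d, n_boot=1, seed=0)
        assert est.ci_low == est.ci_high

    def test_stratified_estimates_with_pooled_fallback(self):
        rng = np.random.default_rng(4)
        d = lognormal_mixture(rng, 1200)
        strata = np.array(
            ["2019-HOCH"] * 1100 + ["2019-KVPE"] * 40 + ["2020-HOCH"] * 60
        )
        out = bootstrap_by_stratum(d, strata, n_boot=50, seed=0)
        assert set(out) == {"pooled", "2019-HOCH", "2019-KVPE", "2020-HOCH"}
        big = out["2019-HOCH"]
        assert big.ci_low <= big.antimode <= big.ci_high
        # the 40-duration stratum is below the floor: pooled value reused
        assert out["2019-KVPE"].antimode == out["pooled"].antimode
        assert out["2019-KVPE"].stratum == "2019-KVPE"

    def test_ci_width_shrinks_with_n(self):
        rng = np.random.default_rng(3)
        widths = {500: [], 5000: []}
        for n in widths:
            for _ in range(20):
                d = lognormal_mixture(rng, n)
                est = bootstrap_threshold(d, n_boot=100, seed=rng)
                widths[n].append(est.ci_high - est.ci_low)
        assert np.median(widths[5000]) < np.median(widths[500])


class TestClassifyRecesses:
    def _rec(self, dur):
        onset = START
        return Recess("N1", onset, onset + pd.Timedelta(minutes=dur), dur)

    def test_partition_and_boundary(self):
        recs = [self._rec(d) for d in (7, 119, 119.3, 120, 340)]
        out = classify_recesses(recs, 119.3)
        labels = [r.recess_class for r in out]
        assert labels == ["short", "short", "extended", "extended", "extended"]
        assert all(r.recess_class in ("short", "extended") for r in out)
        n_short = sum(r.recess_class == "short" for r in out)
        assert n_short + sum(r.recess_class == "extended" for r in out) == len(out)

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            classify_recesses([], 0.0)


class TestAssignStrategy:
    def _stats(self, rates, durs, nest="N1"):
        return pd.DataFrame(
            {
                "nest_id": nest,
                "date": pd.date_range(START, periods=len(rates)),
                "n_recesses": rates,
                "mean_duration": durs,
            }
        )

    # discriminant separating ~23.6/day (uniparental) from ~9.6/day regimes
    DISC = StrategyDiscriminant(
        intercept=-16.0, coef_n_recesses=1.0, coef_mean_duration=0.0
    )

    def test_uniparental_regime(self):
        rng = np.random.default_rng(0)
        stats_ = self._stats(rng.normal(23.6, 3, 8), rng.normal(9, 2, 8))
        out = assign_strategy(stats_, self.DISC)
        assert out["N1"]["strategy"] == "uniparental"

    def test_biparental_regime(self):
        rng = np.random.default_rng(1)
        stats_ = self._stats(rng.normal(9.6, 2, 8), rng.normal(9, 2, 8))
        out = assign_strategy(stats_, self.DISC)
        assert out["N1"]["strategy"] == "biparental"

    def test_swap_changepoint(self):
        rates = [9, 10, 9, 8, 24, 23, 25, 22]  # biparental then uniparental
        out = assign_strategy(self._stats(rates, [9] * 8), self.DISC)
        assert out["N1"]["strategy"] == "swap"
        assert out["N1"]["changepoint_day_index"] == 4

    def test_constant_days_no_changepoint(self):
        out = assign_strategy(self._stats([24] * 6, [9] * 6), self.DISC)
        assert out["N1"]["strategy"] == "uniparental"
        assert out["N1"]["changepoint_day_index"] is None

    def test_missing_discriminant_error(self):
        with pytest.raises(ValueError, match="discriminant"):
            assign_strategy(self._stats([24], [9]), None)

    def test_discriminant_fitted_on_generator_regimes(self):
        # a linear discriminant fitted on labelled synthetic days separates
        # the generator's two regimes
        rng = np.random.default_rng(5)
        uni = rng.normal(23.6, 3.5, 200)
        bi = rng.normal(9.6, 2.5, 200)
        x = np.concatenate([uni, bi])
        y = np.r_[np.ones(200), np.zeros(200)]
        # midpoint rule from class means (simple trained discriminant)
        cut = 0.5 * (uni.mean() + bi.mean())
        disc = StrategyDiscriminant(-cut, 1.0, 0.0)
        pred = np.array(
            [disc.label(v, 0.0) == "uniparental" for v in x], dtype=float
        )
        assert (pred == y).mean() > 0.97
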