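"""Mixed-model layer: fitting, R2, window AIC, simple slopes / JN bounds."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nestrec.inference import (
    ModelFit,
    ModelSpec,
    fit_mixed_model,
    optimize_time_window,
    r2_nakagawa,
    select_interaction_model,
    simple_slopes_jn,
)


def lmm_data(seed, n_groups=30, m=20, b_t=-7.0, b_m=-3.0, b_tm=0.8, sigma_u=40.0, sigma_e=120.0):
    """Gaussian response with a temp x moderator interaction (raw scale)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_groups):
        u = rng.normal(0, sigma_u)
        bc = rng.normal(57.8, 5.5)
        for _ in range(m):
            t = rng.normal(8, 3)
            mu = 340 + b_t * (t - 8) + b_m * (bc - 57.8) + b_tm * (t - 8) * (bc - 57.8) + u
            rows.append(
                {
                    "nest_id": f"N{i:03d}",
                    "duration": mu + rng.normal(0, sigma_e),
                    "t_mean_6h": t,
                    "body_condition": bc,
                    "sex": "F" if rng.uniform() < 0.5 else "M",
                    "incubation_date": rng.integers(1, 20),
                    "period": "day",
                    "nest_type": "uni",
                }
            )
    return pd.DataFrame(rows)


SPEC = ModelSpec(
    response="duration_extended",
    fixed=["t_mean_6h", "body_condition", "sex", "incubation_date"],
    temp_name="t_mean_6h",
    interaction=True,
)


class TestFitMixedModel:
    def test_gaussian_interaction_recovery(self):
        data = lmm_data(0, n_groups=40, m=50)
        fit = fit_mixed_model(data, SPEC)
        # back-transformed slopes at the moderator mean should be near truth
        sd_t = data["t_mean_6h"].std(ddof=0)
        sd_m = data["body_condition"].std(ddof=0)
        b_tm_raw = fit.coef("t_mean_6h:body_condition") / (sd_t * sd_m)
        assert b_tm_raw == pytest.approx(0.8, rel=0.35)
        assert 0 <= fit.r2_marginal <= fit.r2_conditional <= 1

    def test_null_slopes_have_small_t(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            data = lmm_data(seed, n_groups=15, m=10, b_t=0, b_m=0, b_tm=0)
            fit = fit_mixed_model(data, SPEC)
            t = fit.coef("t_mean_6h") / fit.se("t_mean_6h")
            hits += abs(t) < 3
        assert hits >= 19

    def test_zero_between_group_variance(self):
        data = lmm_data(1, sigma_u=0.0)
        fit = fit_mixed_model(data, SPEC)
        assert fit.sigma_u < 15.0
        assert fit.r2_conditional - fit.r2_marginal < 0.05

    def test_raw_slope_invariant_to_affine_rescaling(self):
        data = lmm_data(2)
        fit1 = fit_mixed_model(data, SPEC)
        data2 = data.copy()
        data2["t_mean_6h"] = data2["t_mean_6h"] * 1.8 + 12.0  # degF-ish
        fit2 = fit_mixed_model(data2, SPEC)
        assert fit1.raw_slope("t_mean_6h") == pytest.approx(
            fit2.raw_slope("t_mean_6h") * 1.8, rel=1e-6
        )

    def test_needs_two_groups(self):
        data = lmm_data(3).assign(nest_id="N000")
        with pytest.raises(ValueError):
            fit_mixed_model(data, SPEC)


class TestR2Nakagawa:
    def test_plugin_values(self):
        r2 = r2_nakagawa(1.0, 1.0, 2.0)
        assert r2["marginal"] == pytest.approx(0.25)
        assert r2["conditional"] == pytest.approx(0.50)

    def test_zero_fixed_variance(self):
        assert r2_nakagawa(0.0, 1.0, np.pi**2 / 3)["marginal"] == 0.0

    def test_logit_fit_matches_direct_variance_computation(self):
        # occurrence-type fit: var_fixed must equal var of the fitted
        # linear predictor computed by brute force on the design
        rng = np.random.default_rng(4)
        from scipy.special import expit

        rows = []
        for i in range(40):
            u = rng.normal(0, 1.0)
            for _ in range(80):
                t = rng.normal(8, 2.5)
                p = expit(-2.2 - 0.3 * t + u)
                rows.append(
                    {
                        "nest_id": f"N{i}",
                        "extended": int(rng.uniform() < p),
                        "t_mean_12h": t,
                    }
                )
        data = pd.DataFrame(rows)
        spec = ModelSpec(
            response="extended_flag", fixed=["t_mean_12h"], temp_name="t_mean_12h"
        )
        fit = fit_mixed_model(data, spec)
        z = (data["t_mean_12h"] - data["t_mean_12h"].mean()) / data[
            "t_mean_12h"
        ].std(ddof=0)
        eta = fit.coef("intercept") + fit.coef("t_mean_12h") * z.to_numpy()
        assert fit.var_fixed == pytest.approx(np.var(eta), abs=0.02)
        total = fit.var_fixed + fit.sigma_u**2 + np.pi**2 / 3
        assert fit.r2_marginal == pytest.approx(fit.var_fixed / total, abs=1e-9)


class TestOptimizeTimeWindow:
    def test_identical_columns_identical_aic(self):
        data = lmm_data(5)
        for h in (1, 12):
            data[f"t_mean_{h}h"] = data["t_mean_6h"]
        spec = ModelSpec(
            response="duration_extended",
            fixed=["t_mean_6h", "body_condition", "sex"],
            temp_name="t_mean_6h",
        )
        tab, supported, fits = optimize_time_window(data, spec, windows=(1, 6, 12))
        assert tab["aic"].nunique() == 1
        assert set(supported) == {1, 6, 12}
        assert tab["n_obs"].nunique() == 1


class TestSelectInteraction:
    def test_tie_breaks_to_simpler(self):
        data = lmm_data(6, b_tm=0.0)
        spec_no = ModelSpec(
            response="duration_extended",
            fixed=["t_mean_6h", "body_condition"],
            temp_name="t_mean_6h",
        )
        # identical specs: marginal R2 equal, tie goes to "without"
        sel = select_interaction_model(data, spec_no, spec_no)
        assert not sel["interaction_retained"]
        assert sel["chosen"].spec == spec_no


def fabricate_fit(b_t, b_tm, v_t, v_tm, cov, alpha_for_t2=None):
    """ModelFit with a known 2x2 coefficient covariance (identity scaling)."""
    names = ["intercept", "t", "m", "t:m"]
    params = np.array([0.0, b_t, 0.0, b_tm])
    C = np.zeros((4, 4))
    C[1, 1], C[3, 3] = v_t, v_tm
    C[1, 3] = C[3, 1] = cov
    spec = ModelSpec(
        response="duration_extended",
        fixed=["t", "m"],
        temp_name="t",
        moderator_name="m",
        interaction=True,
    )
    return ModelFit(
        spec=spec, names=names, params=params,
        bse=np.sqrt(np.diag(C)), cov_params=C,
        pvalues=np.ones(4), df_method="normal", df_resid=float("inf"),
        sigma_u=0.0, sigma_resid=1.0, llf=0.0, aic=0.0,
        r2_marginal=0.1, r2_conditional=0.2, n_obs=100, n_groups=10,
        converged=True, singular=False, scaling={},
    )


class TestSimpleSlopesJN:
    ALPHA_T2 = 2 * stats.norm.sf(2.0)  # alpha giving critical value exactly 2

    def test_closed_form_oracle(self):
        # (-2 + m)^2 = 4 (0.04 + 0.01 m^2) solved by the quadratic formula
        fit = fabricate_fit(b_t=-2.0, b_tm=1.0, v_t=0.04, v_tm=0.01, cov=0.0)
        res = simple_slopes_jn(fit, "t", "m", alpha=self.ALPHA_T2, fdr=False)
        a, b, c = 1 - 4 * 0.01, 2 * (-2.0) * 1.0, 4 - 4 * 0.04
        disc = np.sqrt(b * b - 4 * a * c)
        roots = sorted([(-b - disc) / (2 * a), (-b + disc) / (2 * a)])
        assert res.jn_bounds[0] == pytest.approx(roots[0], abs=1e-6)
        assert res.jn_bounds[1] == pytest.approx(roots[1], abs=1e-6)

    def test_no_interaction_term_error(self):
        fit = fabricate_fit(-2.0, 1.0, 0.04, 0.01, 0.0)
        fit.names[3] = "other"
        with pytest.raises(ValueError):
            simple_slopes_jn(fit, "t", "m")

    def test_zero_interaction_slope_constant_no_bound(self):
        fit = fabricate_fit(b_t=-2.0, b_tm=0.0, v_t=0.04, v_tm=0.0, cov=0.0)
        res = simple_slopes_jn(
            fit, "t", "m", probe_values={"a": -1.0, "b": 2.0}, alpha=0.05, fdr=False
        )
        assert res.jn_bounds is None
        assert res.significant_region == "everywhere"
        slopes = [v["slope_per_degC"] for v in res.slopes.values()]
        assert slopes[0] == pytest.approx(slopes[1])

    def test_bracket_property_between_roots(self):
        fit = fabricate_fit(b_t=-2.0, b_tm=1.0, v_t=0.04, v_tm=0.01, cov=0.005)
        res = simple_slopes_jn(fit, "t", "m", alpha=0.05, fdr=False)
        lo, hi = res.jn_bounds
        tcrit = res.t_crit
        for m in np.linspace(lo + 1e-6, hi - 1e-6, 7):
            s = -2.0 + 1.0 * m
            v = 0.04 + m * m * 0.01 + 2 * m * 0.005
            assert abs(s) / np.sqrt(v) < tcrit
        for m in (lo - 0.5, hi + 0.5):
            s = -2.0 + 1.0 * m
            v = 0.04 + m * m * 0.01 + 2 * m * 0.005
            assert abs(s) / np.sqrt(v) > tcrit

    def test_fdr_bound_is_more_conservative(self):
        # FDR-adjusted critical value >= unadjusted, so the significant
        # moderator region shrinks (upper bound moves down for a negative
        # temperature effect fading with the moderator)
        data = lmm_data(7, b_tm=2.0, sigma_e=80.0)
        fit = fit_mixed_model(data, SPEC)
        obs = data["body_condition"].to_numpy()
        res = simple_slopes_jn(fit, moderator_obs=obs, alpha=0.05, fdr=True)
        assert res.t_crit_fdr is None or res.t_crit_fdr >= res.t_crit
        if res.jn_bounds and res.jn_bounds_fdr:
            # larger critical value widens the non-significant interval
            lo, hi = res.jn_bounds
            lof, hif = res.jn_bounds_fdr
            assert lof <= lo + 1e-9 and hif >= hi - 1e-9

    def test_probe_slopes_at_min_median_max(self):
        data = lmm_data(8)
        fit = fit_mixed_model(data, SPEC)
        obs = data["body_condition"].to_numpy()
        res = simple_slopes_jn(fit, moderator_obs=obs)
        assert set(res.probe_values) == {"min", "median", "max"}
        assert res.probe_values["min"] == pytest.approx(obs.min())
        # slope becomes less negative as condition improves (b_tm > 0)
        assert (
            res.slopes["min"]["slope_per_degC"]
            < res.slopes["max"]["slope_per_degC"]
        )
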