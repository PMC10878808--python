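"""Mixed-model inference for recess occurrence, duration and daily totals.

Three model families, all with a nest-identity random intercept to absorb
the repeated-measures design:

* occurrence of an extended (vs short) recess — logistic GLMM;
* duration of extended / short recesses — Gaussian LMM;
* total daily duration of recesses (TDR), for days with and without
  extended recesses — Gaussian LMM.

Numeric predictors are Z-scored before fitting; all models are fitted by
maximum likelihood so AICs are comparable across fixed-effect structures
(the pre-recess temperature window is chosen by AIC).  Variance explained
is summarized with marginal/conditional R2 for mixed models, and
temperature-by-condition interactions are probed with simple slopes and
Johnson-Neyman intervals, optionally with a false-discovery-rate adjusted
critical value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from nestrec.glmm import fit_logistic_glmm

BINOMIAL_RESPONSES = {"extended_flag"}
RESPONSE_COLUMNS = {
    "extended_flag": "extended",
    "duration_extended": "duration",
    "duration_short": "duration",
    "tdr_with_ext": "tdr",
    "tdr_without_ext": "tdr",
}


@dataclass
class ModelSpec:
    """Specification of one mixed model.

    ``fixed`` lists covariate column names; categorical columns (object
    dtype) are dummy-coded with the first level as reference.  When
    ``interaction`` is true, the product of the Z-scored ``temp_name`` and
    ``moderator_name`` columns is added.
    """

    response: str
    fixed: list[str]
    temp_name: str | None = None  # e.g. "t_mean_12h"; must appear in fixed
    moderator_name: str = "body_condition"
    interaction: bool = False
    group_col: str = "nest_id"
    scale_numeric: bool = True

    @property
    def family(self) -> str:
        return "binomial-logit" if self.response in BINOMIAL_RESPONSES else "gaussian-identity"

    @property
    def response_col(self) -> str:
        return RESPONSE_COLUMNS.get(self.response, self.response)

    def columns_used(self) -> list[str]:
        cols = list(self.fixed)
        if self.interaction:
            for c in (self.temp_name, self.moderator_name):
                if c not in cols:
                    cols.append(c)
        return cols


@dataclass
class ModelFit:
    """A fitted mixed model with everything downstream analyses need."""

    spec: ModelSpec
    names: list[str]
    params: np.ndarray
    bse: np.ndarray
    cov_params: np.ndarray  # fixed-effects covariance
    pvalues: np.ndarray
    df_method: str  # "residual" (flagged fallback) or "normal"
    df_resid: float
    sigma_u: float
    sigma_resid: float  # NaN for binomial
    llf: float
    aic: float
    r2_marginal: float
    r2_conditional: float
    n_obs: int
    n_groups: int
    converged: bool
    singular: bool
    scaling: dict = field(default_factory=dict)  # name -> (mean, sd)
    var_fixed: float = 0.0

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def se(self, name: str) -> float:
        return float(self.bse[self.names.index(name)])

    def raw_slope(self, name: str) -> float:
        """Back-transform a Z-scale slope to per-raw-unit of the predictor."""
        mu_sd = self.scaling.get(name)
        return self.coef(name) / mu_sd[1] if mu_sd else self.coef(name)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "se": self.bse, "p": self.pvalues},
            index=self.names,
        )


def _design(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, list[str], dict, pd.DataFrame]:
    """Build the fixed-effects design matrix (intercept first, Z-scored)."""
    cols = spec.columns_used()
    need = [spec.response_col, spec.group_col] + cols
    d = data.dropna(subset=[c for c in need if c in data.columns]).copy()
    if d.empty:
        raise ValueError("no complete cases for model")
    names: list[str] = ["intercept"]
    mats = [np.ones(len(d))]
    scaling: dict = {}
    zcols: dict[str, np.ndarray] = {}
    for c in cols:
        col = d[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:
                names.append(f"{c}[{lev}]")
                mats.append((col.astype(str) == lev).to_numpy(float))
        else:
            v = col.to_numpy(float)
            if spec.scale_numeric:
                mu, sd = float(v.mean()), float(v.std(ddof=0))
                sd = sd if sd > 0 else 1.0
                scaling[c] = (mu, sd)
                v = (v - mu) / sd
            zcols[c] = v
            names.append(c)
            mats.append(v)
    if spec.interaction:
        t, m = spec.temp_name, spec.moderator_name
        names.append(f"{t}:{m}")
        mats.append(zcols[t] * zcols[m])
    X = np.column_stack(mats)
    return X, names, scaling, d


def r2_nakagawa(
    var_fixed: float,
    var_random: float,
    var_resid: float,
) -> dict[str, float]:
    """Marginal and conditional R2 for mixed models.

    marginal = var_fixed / total, conditional = (var_fixed + var_random) /
    total, with total = var_fixed + var_random + var_resid.  For a
    binomial-logit model pass the theoretical latent-scale residual
    variance pi^2 / 3.
    """
    total = var_fixed + var_random + var_resid
    if total <= 0:
        return {"marginal": 0.0, "conditional": 0.0}
    return {
        "marginal": var_fixed / total,
        "conditional": (var_fixed + var_random) / total,
    }


def fit_mixed_model(data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Fit the model described by ``spec`` on the complete cases of ``data``.

    Binomial responses use the in-package Gauss-Hermite logistic GLMM;
    Gaussian responses use a linear mixed model fitted by ML (REML off, so
    AICs are comparable across fixed-effect structures).  LMM p-values use
    residual degrees of freedom (flagged in ``df_method``).
    """
    X, names, scaling, d = _design(data, spec)
    y = d[spec.response_col].to_numpy(float)
    groups = d[spec.group_col].to_numpy()
    if len(set(groups)) < 2:
        raise ValueError("need >= 2 groups (nests)")

    if spec.family == "binomial-logit":
        res = fit_logistic_glmm(X, y, groups, names=names)
        params, bse, cov = res.beta, res.bse, res.cov_beta
        with np.errstate(invalid="ignore"):
            z = np.divide(params, bse, out=np.zeros_like(params), where=bse > 0)
        pvals = 2 * stats.norm.sf(np.abs(z))
        var_resid = np.pi**2 / 3.0
        sigma_resid = float("nan")
        sigma_u, llf, aic = res.sigma_u, res.llf, res.aic
        converged, singular = res.converged, res.singular
        df_method, df_resid = "normal", float("inf")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mod = sm.MixedLM(y, X, groups=groups)
            res = None
            err: Exception | None = None
            for method in (["lbfgs", "powell"], ["powell"], ["nm"], ["cg"]):
                try:
                    res = mod.fit(reml=False, method=method)
                    break
                except (np.linalg.LinAlgError, ValueError) as exc:
                    err = exc
            if res is None:
                raise RuntimeError(f"LMM did not converge: {err}") from err
        params = np.asarray(res.fe_params, float)
        cov = np.asarray(res.cov_params())[: len(names), : len(names)]
        bse = np.sqrt(np.clip(np.diag(cov), 0, None))
        df_resid = float(len(d) - len(names))
        with np.errstate(invalid="ignore"):
            t = np.divide(params, bse, out=np.zeros_like(params), where=bse > 0)
        pvals = 2 * stats.t.sf(np.abs(t), df_resid)
        sigma_u = float(np.sqrt(max(np.asarray(res.cov_re)[0, 0], 0.0)))
        sigma_resid = float(np.sqrt(res.scale))
        var_resid = sigma_resid**2
        llf = float(res.llf)
        k = len(names) + 2  # fixed effects + two variance components
        aic = 2 * k - 2 * llf
        converged = bool(res.converged)
        singular = sigma_u**2 < 1e-8 * max(var_resid, 1e-12)
        df_method = "residual"

    var_fixed = float(np.var(X @ params))
    r2 = r2_nakagawa(var_fixed, sigma_u**2, var_resid)
    return ModelFit(
        spec=spec,
        names=names,
        params=params,
        bse=bse,
        cov_params=cov,
        pvalues=pvals,
        df_method=df_method,
        df_resid=df_resid,
        sigma_u=float(sigma_u),
        sigma_resid=sigma_resid,
        llf=float(llf),
        aic=float(aic),
        r2_marginal=float(r2["marginal"]),
        r2_conditional=float(r2["conditional"]),
        n_obs=len(d),
        n_groups=len(set(groups)),
        converged=converged,
        singular=singular,
        scaling=scaling,
        var_fixed=var_fixed,
    )


def optimize_time_window(
    data: pd.DataFrame,
    base_spec: ModelSpec,
    windows: Sequence[int] = (1, 2, 6, 12, 24),
) -> tuple[pd.DataFrame, list[int], dict[int, ModelFit]]:
    """Fit one model per pre-recess temperature window and compare by AIC.

    All windows are fitted on the identical complete-case intersection (AIC
    is meaningless across differing data), enforced with a hard error.
    Returns the AIC table (sorted, with delta AIC and R2), the windows
    within delta AIC <= 2 of the best (equally supported), and the fits.
    """
    win_cols = [f"t_mean_{int(h)}h" for h in windows]
    other = [c for c in base_spec.fixed if c not in win_cols]
    need = [base_spec.response_col, base_spec.group_col] + other + win_cols
    if base_spec.interaction:
        need.append(base_spec.moderator_name)
    d = data.dropna(subset=[c for c in dict.fromkeys(need) if c in data.columns])
    fits: dict[int, ModelFit] = {}
    for h in windows:
        col = f"t_mean_{int(h)}h"
        spec = replace(base_spec, fixed=other + [col], temp_name=col)
        fits[h] = fit_mixed_model(d, spec)
    ns = {f.n_obs for f in fits.values()}
    if len(ns) != 1:
        raise RuntimeError(f"window fits used differing n: {ns}; AIC incomparable")
    tab = pd.DataFrame(
        {
            "window_hours": list(fits),
            "aic": [fits[h].aic for h in fits],
            "r2_marginal": [fits[h].r2_marginal for h in fits],
            "r2_conditional": [fits[h].r2_conditional for h in fits],
            "n_obs": [fits[h].n_obs for h in fits],
        }
    )
    tab["delta_aic"] = tab["aic"] - tab["aic"].min()
    tab = tab.sort_values("aic").reset_index(drop=True)
    supported = [int(h) for h in tab.loc[tab["delta_aic"] <= 2.0, "window_hours"]]
    return tab, supported, fits


def select_interaction_model(
    data: pd.DataFrame, spec_with: ModelSpec, spec_without: ModelSpec
) -> dict:
    """Choose between interaction and no-interaction specs by marginal R2.

    Ties break toward the simpler (no-interaction) model.  Both fits and
    their AICs are returned for transparency.
    """
    fit_with = fit_mixed_model(data, spec_with)
    fit_without = fit_mixed_model(data, spec_without)
    use_interaction = fit_with.r2_marginal > fit_without.r2_marginal + 1e-12
    chosen = fit_with if use_interaction else fit_without
    return {
        "chosen_spec": chosen.spec,
        "chosen": chosen,
        "interaction_retained": bool(use_interaction),
        "fit_with": fit_with,
        "fit_without": fit_without,
        "r2_marginal_with": fit_with.r2_marginal,
        "r2_marginal_without": fit_without.r2_marginal,
        "aic_with": fit_with.aic,
        "aic_without": fit_without.aic,
    }


@dataclass
class SimpleSlopesResult:
    """Simple slopes and Johnson-Neyman bounds for a temp x moderator fit.

    Slopes are reported per raw degC at raw moderator values; JN bounds are
    raw moderator values where the conditional temperature slope changes
    significance.  ``jn_bounds_fdr`` uses the FDR-inflated critical value.
    """

    probe_values: dict[str, float]  # label -> raw moderator value
    slopes: dict[str, dict]  # label -> {slope, se, t, p, significant}
    jn_bounds: tuple[float, float] | None
    jn_bounds_fdr: tuple[float, float] | None
    significant_region: str  # "outside" | "inside" | "everywhere" | "nowhere"
    alpha: float
    t_crit: float
    t_crit_fdr: float | None


def _jn_roots(
    b_t: float, b_tm: float, v_t: float, v_tm: float, c_ttm: float, tcrit: float
) -> tuple[tuple[float, float] | None, str]:
    """Roots of s(m)^2 = t*^2 Var s(m) with s(m) = b_t + b_tm m (Z scale)."""
    a = b_tm**2 - tcrit**2 * v_tm
    b = 2 * b_t * b_tm - 2 * tcrit**2 * c_ttm
    c = b_t**2 - tcrit**2 * v_t
    disc = b**2 - 4 * a * c
    if abs(a) < 1e-300:
        return None, "everywhere" if c > 0 else "nowhere"
    if disc < 0:
        # no real roots: significance never flips
        return None, "everywhere" if a > 0 else "nowhere"
    r1 = (-b - np.sqrt(disc)) / (2 * a)
    r2 = (-b + np.sqrt(disc)) / (2 * a)
    lo, hi = sorted((r1, r2))
    # a > 0: |t(m)| > t* outside (lo, hi); a < 0: inside
    return (lo, hi), ("outside" if a > 0 else "inside")


def simple_slopes_jn(
    fit: ModelFit,
    temp_name: str | None = None,
    moderator_name: str | None = None,
    probe_values: dict[str, float] | None = None,
    moderator_obs: np.ndarray | None = None,
    alpha: float = 0.05,
    fdr: bool = True,
) -> SimpleSlopesResult:
    """Probe a temperature x body-condition interaction.

    The conditional slope of temperature at moderator value m (Z scale) is
    s(m) = b_T + b_TxM * m with variance Var(b_T) + m^2 Var(b_TxM) +
    2 m Cov.  Johnson-Neyman bounds are the moderator values where
    |s|/SE = t*.  With ``fdr`` the critical value is additionally derived
    from a Benjamini-Hochberg pass over the conditional-slope p-values at
    the observed moderator values, which controls the false discovery rate
    across the moderator range; both bounds are always reported.

    ``probe_values`` defaults to min/median/max of ``moderator_obs`` (raw
    units); slopes are returned per raw degC.
    """
    spec = fit.spec
    temp_name = temp_name or spec.temp_name
    moderator_name = moderator_name or spec.moderator_name
    int_name = f"{temp_name}:{moderator_name}"
    if int_name not in fit.names:
        raise ValueError(f"fit has no interaction term {int_name!r}")
    i_t = fit.names.index(temp_name)
    i_tm = fit.names.index(int_name)
    b_t, b_tm = float(fit.params[i_t]), float(fit.params[i_tm])
    v_t = float(fit.cov_params[i_t, i_t])
    v_tm = float(fit.cov_params[i_tm, i_tm])
    c_ttm = float(fit.cov_params[i_t, i_tm])

    df = fit.df_resid
    tcrit = (
        float(stats.norm.ppf(1 - alpha / 2))
        if not np.isfinite(df)
        else float(stats.t.ppf(1 - alpha / 2, df))
    )
    mu_m, sd_m = fit.scaling.get(moderator_name, (0.0, 1.0))
    mu_t, sd_t = fit.scaling.get(temp_name, (0.0, 1.0))

    def to_raw(mz: float) -> float:
        return mu_m + sd_m * mz

    def to_z(m: float) -> float:
        return (m - mu_m) / sd_m

    def slope_var(mz: float) -> tuple[float, float]:
        s = b_t + b_tm * mz
        v = v_t + mz**2 * v_tm + 2 * mz * c_ttm
        return s, max(v, 0.0)

    roots_z, region = _jn_roots(b_t, b_tm, v_t, v_tm, c_ttm, tcrit)
    jn = tuple(sorted(to_raw(r) for r in roots_z)) if roots_z else None

    # FDR-adjusted critical value from a BH pass at observed moderator values
    t_crit_fdr = None
    jn_fdr = None
    if fdr and moderator_obs is not None and len(moderator_obs) > 0:
        mz = (np.asarray(moderator_obs, float) - mu_m) / sd_m
        sv = np.array([slope_var(m) for m in mz])
        with np.errstate(divide="ignore", invalid="ignore"):
            tt = np.abs(sv[:, 0]) / np.sqrt(sv[:, 1])
        pp = (
            2 * stats.norm.sf(tt)
            if not np.isfinite(df)
            else 2 * stats.t.sf(tt, df)
        )
        order = np.sort(pp)
        m_tot = order.size
        thresh = alpha * np.arange(1, m_tot + 1) / m_tot
        passing = np.where(order <= thresh)[0]
        if passing.size:
            p_star = float(thresh[passing.max()])
            t_crit_fdr = (
                float(stats.norm.ppf(1 - p_star / 2))
                if not np.isfinite(df)
                else float(stats.t.ppf(1 - p_star / 2, df))
            )
            roots_fdr, _ = _jn_roots(b_t, b_tm, v_t, v_tm, c_ttm, t_crit_fdr)
            if roots_fdr:
                jn_fdr = tuple(sorted(to_raw(r) for r in roots_fdr))

    if probe_values is None:
        if moderator_obs is not None and len(moderator_obs) > 0:
            arr = np.asarray(moderator_obs, float)
            probe_values = {
                "min": float(arr.min()),
                "median": float(np.median(arr)),
                "max": float(arr.max()),
            }
        else:
            probe_values = {"mean": mu_m}
    slopes = {}
    for label, m in probe_values.items():
        s, v = slope_var(to_z(m))
        se = np.sqrt(v)
        tval = s / se if se > 0 else np.inf
        p = (
            2 * stats.norm.sf(abs(tval))
            if not np.isfinite(df)
            else 2 * stats.t.sf(abs(tval), df)
        )
        slopes[label] = {
            "moderator": m,
            "slope_per_degC": s / sd_t,  # back to raw temperature units
            "se_per_degC": se / sd_t,
            "t": float(tval),
            "p": float(p),
            "significant": bool(abs(tval) > tcrit),
        }
    return SimpleSlopesResult(
        probe_values=probe_values,
        slopes=slopes,
        jn_bounds=jn,
        jn_bounds_fdr=jn_fdr,
        significant_region=region,
        alpha=alpha,
        t_crit=tcrit,
        t_crit_fdr=t_crit_fdr,
    )


def occurrence_effect_per_degree(
    fit: ModelFit,
    temp_name: str,
    temp_range: tuple[float, float],
    scale: str = "probability",
) -> float:
    """Average relative change in extended-recess risk per +1 degC.

    ``scale="odds"`` returns exp(raw slope) - 1 (constant over the range).
    ``scale="probability"`` averages the relative change in the predicted
    probability per +1 degC over the observed temperature range, holding
    other predictors at their reference (mean / baseline) values.
    """
    b_raw = fit.raw_slope(temp_name)
    if scale == "odds":
        return float(np.exp(b_raw) - 1.0)
    mu_t, sd_t = fit.scaling.get(temp_name, (0.0, 1.0))
    b0 = fit.coef("intercept")
    ts = np.arange(np.floor(temp_range[0]), np.ceil(temp_range[1]) + 1e-9)
    eta = b0 + fit.coef(temp_name) * (ts - mu_t) / sd_t
    p = 1.0 / (1.0 + np.exp(-eta))
    rel = np.diff(p) / p[:-1]
    return float(rel.mean())
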