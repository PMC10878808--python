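"""End-to-end orchestration: simulate/ingest -> detect -> classify -> fit.

``run_pipeline`` executes the full analysis on either a synthetic study
bundle or a directory of logger CSVs, and returns a JSON-serializable
report: recess counts, the antimode threshold with its bootstrap CI, the
AIC time-window tables, model coefficients with marginal/conditional R2,
Johnson-Neyman bounds, and an exclusion ledger whose counts are
conservative (records in = records out + excluded, per stage).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from nestrec import detection, inference
from nestrec.classification import bootstrap_threshold, classify_recesses
from nestrec.covariates import build_recess_covariates, scaled_mass_index
from nestrec.detection import (
    DetectionParams,
    apply_quality_filters,
    build_nest_days,
    detect_recesses,
    flag_captures,
    recesses_to_frame,
)
from nestrec.inference import (
    ModelSpec,
    fit_mixed_model,
    occurrence_effect_per_degree,
    optimize_time_window,
    select_interaction_model,
    simple_slopes_jn,
)
from nestrec.synthetic import GeneratorParams, StudyBundle, simulate_study
from nestrec.timeseries_io import daily_ground_stats

logger = logging.getLogger(__name__)

BASE_FIXED = ["body_condition", "sex", "incubation_date", "period", "nest_type"]
TDR_FIXED = ["t_mean_daily", "body_condition", "sex", "incubation_date", "nest_type"]


@dataclass
class RunConfig:
    """Fully serializable run configuration; (config, seed) fixes all outputs."""

    seed: int = 0
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    n_boot: int = 1000
    windows: tuple[int, ...] = (1, 2, 6, 12, 24)
    alpha: float = 0.05
    min_model_obs: int = 30
    manual_exclusions: tuple = ()
    capture_events: tuple = ()
    output_dir: str | None = None


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Timestamp):
        return obj.isoformat()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _fit_report(fit: inference.ModelFit) -> dict:
    return {
        "response": fit.spec.response,
        "coefficients": {
            n: {"coef": float(b), "se": float(s), "p": float(p)}
            for n, b, s, p in zip(fit.names, fit.params, fit.bse, fit.pvalues)
        },
        "sigma_nest": fit.sigma_u,
        "sigma_resid": None if not np.isfinite(fit.sigma_resid) else fit.sigma_resid,
        "aic": fit.aic,
        "r2_marginal": fit.r2_marginal,
        "r2_conditional": fit.r2_conditional,
        "n_obs": fit.n_obs,
        "n_nests": fit.n_groups,
        "df_method": fit.df_method,
        "converged": fit.converged,
        "singular": fit.singular,
    }


def summarize_recesses(
    recess_frame: pd.DataFrame, strategies: dict[str, str] | None = None
) -> dict:
    """Descriptive summary: per-strategy daily rates, extended proportions,
    duration statistics.  ``strategies`` maps nest_id -> strategy label."""
    out: dict = {"n_recesses": int(len(recess_frame))}
    if recess_frame.empty:
        out.update({"per_strategy": {}, "duration": {}, "extended": {}})
        return out
    f = recess_frame.copy()
    f["strategy"] = (
        f["nest_id"].map(strategies) if strategies else "uniparental"
    )
    per_strategy = {}
    for strat, grp in f.groupby("strategy"):
        days = grp.groupby(["nest_id", "day_of_onset"]).size()
        per_strategy[str(strat)] = {
            "n_recesses": int(len(grp)),
            "n_nests": int(grp["nest_id"].nunique()),
            "recesses_per_day_mean": float(days.mean()),
            "recesses_per_day_range": [int(days.min()), int(days.max())],
        }
    ext = f[f["recess_class"] == "extended"]["duration"]
    out["per_strategy"] = per_strategy
    out["duration"] = {
        "mean": float(f["duration"].mean()),
        "median": float(f["duration"].median()),
        "range": [float(f["duration"].min()), float(f["duration"].max())],
    }
    out["extended"] = {
        "n": int(len(ext)),
        "proportion_pct": float(100.0 * len(ext) / len(f)),
        "duration_mean": float(ext.mean()) if len(ext) else None,
        "duration_median": float(ext.median()) if len(ext) else None,
        "duration_range": [float(ext.min()), float(ext.max())] if len(ext) else None,
    }
    return out


def _model_block(
    data: pd.DataFrame,
    response: str,
    windows: Sequence[int],
    alpha: float,
    min_obs: int,
    temp_windows: Sequence[int] | None = None,
) -> dict:
    """Window optimization + interaction selection + JN probing for one family."""
    if len(data) < min_obs or data["nest_id"].nunique() < 3:
        return {"skipped": f"insufficient data (n={len(data)})"}
    temp_windows = list(temp_windows or windows)
    base = ModelSpec(response=response, fixed=BASE_FIXED + [f"t_mean_{temp_windows[0]}h"],
                     temp_name=f"t_mean_{temp_windows[0]}h")
    tab, supported, fits = optimize_time_window(data, base, temp_windows)
    best_h = int(tab.iloc[0]["window_hours"])
    tcol = f"t_mean_{best_h}h"
    spec_no = ModelSpec(response=response, fixed=BASE_FIXED + [tcol], temp_name=tcol)
    spec_int = replace(spec_no, interaction=True)
    sel = select_interaction_model(data, spec_int, spec_no)
    chosen = sel["chosen"]
    block = {
        "aic_table": tab.to_dict(orient="records"),
        "supported_windows": supported,
        "selected_window_hours": best_h,
        "interaction_retained": sel["interaction_retained"],
        "r2_marginal_with": sel["r2_marginal_with"],
        "r2_marginal_without": sel["r2_marginal_without"],
        "fit": _fit_report(chosen),
    }
    if sel["interaction_retained"]:
        mod_obs = data.dropna(subset=[tcol, "body_condition"])["body_condition"].to_numpy()
        ss = simple_slopes_jn(
            sel["fit_with"], moderator_obs=mod_obs, alpha=alpha
        )
        block["simple_slopes"] = {
            "slopes": ss.slopes,
            "jn_bounds": ss.jn_bounds,
            "jn_bounds_fdr": ss.jn_bounds_fdr,
            "significant_region": ss.significant_region,
            "t_crit": ss.t_crit,
            "t_crit_fdr": ss.t_crit_fdr,
        }
    return block


def run_pipeline(
    config: RunConfig | None = None, bundle: StudyBundle | None = None
) -> dict:
    """Execute every stage and return the consolidated report (JSON-ready).

    A synthetic bundle is generated from ``config.generator`` unless one is
    passed in.  When ``config.output_dir`` is set, stage artifacts
    (recess/nest-day/covariate tables, report.json) are written there.
    """
    config = config or RunConfig()
    if bundle is None:
        bundle = simulate_study(config.generator, seed=config.seed)
    ledger: list[dict] = []
    report: dict = {"seed": config.seed}

    # --- detection ---------------------------------------------------------
    all_recesses = []
    nest_days = []
    monitored = {}
    for trace in bundle.traces:
        rec = detect_recesses(trace, config.detection, detection.MAX_DROP)
        rec = flag_captures(rec, config.capture_events)
        all_recesses.extend(rec)
        nest_days.extend(build_nest_days(trace, rec, config.detection))
        monitored[trace.nest_id or trace.logger_id] = trace.monitored_hours
    n_detected = len(all_recesses)
    n_capture = sum(r.is_capture_artifact for r in all_recesses)
    kept_days, exclusion_report = apply_quality_filters(
        nest_days,
        config.detection,
        monitored_hours=monitored,
        manual_exclusions=config.manual_exclusions,
    )
    kept_day_keys = {(nd.nest_id, nd.date) for nd in kept_days}
    live = [
        r
        for r in all_recesses
        if not r.is_capture_artifact and (r.nest_id, r.day_of_onset) in kept_day_keys
    ]
    ledger.append(
        {
            "stage": "detection",
            "records_in": n_detected,
            "records_out": len(live),
            "excluded": {
                "capture_artifact": int(n_capture),
                "quality_filtered_day": int(n_detected - n_capture - len(live)),
            },
        }
    )

    # --- classification ----------------------------------------------------
    durations = [r.duration for r in live]
    threshold = bootstrap_threshold(
        durations, n_boot=config.n_boot, seed=config.seed
    )
    live = classify_recesses(live, threshold.antimode)
    report["threshold"] = {
        "antimode_min": threshold.antimode,
        "modes_min": list(threshold.modes),
        "ci_95": [threshold.ci_low, threshold.ci_high],
        "n_boot": threshold.n_boot,
        "n_failed_boot": threshold.n_failed_boot,
        "bandwidth_log": threshold.bandwidth,
        "scale": threshold.scale,
    }
    ext_by_day: dict = {}
    for r in live:
        if r.recess_class == "extended":
            key = (r.nest_id, r.day_of_onset)
            ext_by_day[key] = ext_by_day.get(key, 0) + 1
    for nd in kept_days:
        nd.n_extended = ext_by_day.get((nd.nest_id, nd.date), 0)

    # --- covariates --------------------------------------------------------
    smi = scaled_mass_index(bundle.morphometrics)
    bc_map = dict(zip(smi["nest_id"], smi["smi"]))
    inc_start = {m.nest_id: m.incubation_start for m in bundle.metadata}
    nest_type = {
        m.nest_id: ("swap" if m.strategy == "swap" else "uni")
        for m in bundle.metadata
    }
    data = build_recess_covariates(
        live,
        bundle.ground,
        body_condition=bc_map,
        sex=bundle.sex,
        nest_type=nest_type,
        incubation_start=inc_start,
        windows=config.windows,
    )
    report["body_condition"] = {
        "median": float(smi["smi"].median()),
        "min": float(smi["smi"].min()),
        "max": float(smi["smi"].max()),
        "b_sma": float(smi["b_sma"].iloc[0]),
        "l0_mm": float(smi["l0"].iloc[0]),
    }

    # --- models ------------------------------------------------------------
    models: dict = {}
    occ = _model_block(
        data, "extended_flag", config.windows, config.alpha, config.min_model_obs
    )
    if "fit" in occ and data["extended"].sum() >= 10:
        h = occ["selected_window_hours"]
        tcol = f"t_mean_{h}h"
        fit_occ = fit_mixed_model(
            data,
            ModelSpec(
                response="extended_flag",
                fixed=BASE_FIXED + [tcol],
                temp_name=tcol,
            ),
        )
        trange = (
            float(data[tcol].min()),
            float(data[tcol].max()),
        )
        occ["temperature_range_degC"] = list(trange)
        occ["prob_change_per_degC"] = occurrence_effect_per_degree(
            fit_occ, tcol, trange, scale="probability"
        )
        occ["odds_change_per_degC"] = occurrence_effect_per_degree(
            fit_occ, tcol, trange, scale="odds"
        )
    models["occurrence_extended"] = occ
    models["duration_extended"] = _model_block(
        data[data["extended"] == 1],
        "duration_extended",
        config.windows,
        config.alpha,
        config.min_model_obs,
    )
    models["duration_short"] = _model_block(
        data[data["extended"] == 0],
        "duration_short",
        config.windows,
        config.alpha,
        config.min_model_obs,
        temp_windows=(1, 2, 6),
    )

    # --- TDR (nest-day scale) ---------------------------------------------
    day_rows = []
    for nd in kept_days:
        gstats = daily_ground_stats(bundle.ground, nd.date)
        start = inc_start.get(nd.nest_id)
        day_rows.append(
            {
                "nest_id": nd.nest_id,
                "date": nd.date,
                "tdr": nd.tdr,
                "n_recesses": nd.n_recesses,
                "n_extended": nd.n_extended or 0,
                "t_mean_daily": gstats["mean"],
                "body_condition": bc_map.get(nd.nest_id, np.nan),
                "sex": bundle.sex.get(nd.nest_id, "unknown"),
                "nest_type": nest_type.get(nd.nest_id, "uni"),
                "incubation_date": (
                    (pd.Timestamp(nd.date) - pd.Timestamp(start)).days
                    if start
                    else np.nan
                ),
            }
        )
    day_table = pd.DataFrame(day_rows)
    report["tdr_summary"] = {}
    for label, response, mask in (
        ("with_extended", "tdr_with_ext", day_table["n_extended"] > 0),
        ("without_extended", "tdr_without_ext", day_table["n_extended"] == 0),
    ):
        sub = day_table[mask]
        report["tdr_summary"][label] = {
            "n_days": int(len(sub)),
            "n_nests": int(sub["nest_id"].nunique()),
            "tdr_mean_min": float(sub["tdr"].mean()) if len(sub) else None,
        }
        models[f"tdr_{label}"] = _tdr_block(sub, response, config)

    report["models"] = models
    strategies = {m.nest_id: m.strategy for m in bundle.metadata}
    rframe = recesses_to_frame(live)
    report["summary"] = summarize_recesses(rframe, strategies)
    report["exclusion_ledger"] = ledger + [
        {"stage": "quality_days", "excluded_days": int(len(exclusion_report))}
    ]

    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        rframe.to_csv(outdir / "recesses.csv", index=False)
        day_table.to_csv(outdir / "nest_days.csv", index=False)
        data.to_csv(outdir / "covariates.csv", index=False)
        exclusion_report.to_csv(outdir / "exclusions.csv", index=False)
        (outdir / "report.json").write_text(
            json.dumps(_jsonable(report), indent=2)
        )
    return _jsonable(report)


def _tdr_block(sub: pd.DataFrame, response: str, config: RunConfig) -> dict:
    """Interaction selection + JN for one TDR model (daily mean temperature)."""
    if len(sub) < config.min_model_obs or sub["nest_id"].nunique() < 3:
        return {"skipped": f"insufficient data (n={len(sub)})"}
    spec_no = ModelSpec(
        response=response, fixed=TDR_FIXED, temp_name="t_mean_daily"
    )
    spec_int = replace(spec_no, interaction=True)
    sel = select_interaction_model(sub, spec_int, spec_no)
    block = {
        "interaction_retained": sel["interaction_retained"],
        "r2_marginal_with": sel["r2_marginal_with"],
        "r2_marginal_without": sel["r2_marginal_without"],
        "fit": _fit_report(sel["chosen"]),
    }
    if sel["interaction_retained"]:
        ss = simple_slopes_jn(
            sel["fit_with"],
            moderator_obs=sub.dropna(subset=["t_mean_daily", "body_condition"])[
                "body_condition"
            ].to_numpy(),
            alpha=config.alpha,
        )
        block["simple_slopes"] = {
            "slopes": ss.slopes,
            "jn_bounds": ss.jn_bounds,
            "jn_bounds_fdr": ss.jn_bounds_fdr,
            "significant_region": ss.significant_region,
            "t_crit": ss.t_crit,
            "t_crit_fdr": ss.t_crit_fdr,
        }
    return block
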