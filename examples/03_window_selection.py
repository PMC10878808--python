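"""Which pre-recess temperature window predicts extended recesses?

Simulates a recess table whose extended-recess occurrence truly depends on
the mean ground temperature over the 12 h before each bout, then fits one
logistic mixed model per candidate window (1, 2, 6, 12, 24 h) and compares
them by AIC.
"""

from nestrec import GeneratorParams, ModelSpec, optimize_time_window, simulate_recess_table

params = GeneratorParams()
table = simulate_recess_table(params, seed=0, n_days=8)

spec = ModelSpec(
    response="extended_flag",
    fixed=["t_mean_12h", "body_condition", "sex", "incubation_date", "period"],
    temp_name="t_mean_12h",
)
aic_table, supported, fits = optimize_time_window(table, spec)

print(aic_table[["window_hours", "aic", "delta_aic", "r2_marginal"]].to_string(index=False))
print(f"\nequally supported windows (delta AIC <= 2): {supported}")
best = int(aic_table.iloc[0]["window_hours"])
fit = fits[best]
print(f"best window: {best} h; temperature slope "
      f"{fit.raw_slope(f't_mean_{best}h'):+.3f} per degC on the log-odds scale")
print(
    "\nThe generating window (12 h) should sit at the top: birds integrate"
    "\nabout half a day of cold before committing to an extended recess."
)
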