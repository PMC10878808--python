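"""Temperature x body-condition interaction on extended-recess duration.

Fits the extended-duration linear mixed model with the interaction, probes
the conditional temperature slope at the minimum / median / maximum body
condition, and reports the Johnson-Neyman bound: the body condition above
which temperature no longer affects duration significantly.
"""

import numpy as np

from nestrec import (
    GeneratorParams,
    ModelSpec,
    fit_mixed_model,
    simple_slopes_jn,
    simulate_recess_table,
)

params = GeneratorParams()
table = simulate_recess_table(params, seed=3, n_days=8)
ext = table[table.extended == 1]
print(f"{len(ext)} extended recesses from {ext.nest_id.nunique()} nests")

spec = ModelSpec(
    response="duration_extended",
    fixed=["t_mean_6h", "body_condition", "sex", "incubation_date"],
    temp_name="t_mean_6h",
    interaction=True,
)
fit = fit_mixed_model(ext, spec)
res = simple_slopes_jn(fit, moderator_obs=ext["body_condition"].to_numpy())

for label, s in res.slopes.items():
    star = "*" if s["significant"] else " "
    print(f"  BC {label:>6} ({s['moderator']:5.1f} g): "
          f"{s['slope_per_degC']:+6.1f} min per degC {star}")
print(f"Johnson-Neyman bounds (body condition): {res.jn_bounds}")
print(f"FDR-adjusted bounds:                    {res.jn_bounds_fdr}")
print(
    "\nBirds in poor condition shorten extended recesses sharply as it"
    "\nwarms; above the JN body-condition bound the temperature effect is"
    "\nno longer distinguishable from zero."
)
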