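"""Detect incubation recesses in a single nest-temperature trace.

Builds one synthetic nest trace (38 degC incubation baseline, off-nest
bouts cooling toward ground temperature), runs the max-drop segmentation
(threshold = daily maximum - 4.5 degC, minimum bout 3 min) and prints the
detected bouts next to the planted truth.
"""

import pandas as pd

from nestrec import GeneratorParams, detect_recesses, simulate_ground, simulate_nest

params = GeneratorParams()
ground = simulate_ground(params, n_days=3, seed=0)
trace, truth = simulate_nest(params, ground, body_condition=57.8, seed=1)

recesses = detect_recesses(trace)

print(f"planted bouts: {len(truth)}, detected: {len(recesses)}\n")
print("first five detected recesses (onset, duration in minutes):")
for r in recesses[:5]:
    print(f"  {r.onset}  {r.duration:5d} min")
print(
    "\nEach row is one off-nest bout: the bird left the nest at `onset` and"
    "\nthe egg temperature stayed >4.5 degC below the daily maximum for"
    "\n`duration` consecutive minutes."
)
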