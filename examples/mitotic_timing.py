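"""Mitotic timing statistics: cumulative-frequency t50 and event fractions.

Simulates NEBD->anaphase-onset durations for a normal condition (median
60 min) and a delayed one (median 96 min), quantized to the 6-min frame
grid and censored at the 10-h imaging window, then summarises t50, the
fraction completing mitosis, and the Mann-Whitney comparison.
"""

import numpy as np

from civa.simulate import sim_timing
from civa.timing import compare_groups, event_fractions, t50, timing_summary

conditions = {"WT": (60, 1), "variant": (96, 2)}
records = []
for cond, (median, seed) in conditions.items():
    recs, _ = sim_timing(("exponential", {"median": median}), n_cells=150,
                         seed=seed, condition=cond)
    records.extend(recs)

summary = timing_summary(records)
print("Per-condition summary (times in minutes):")
print(summary.round(3).to_string(index=False))
# t50 is read off the cumulative step function at 0.5 on the 6-min grid,
# with censored cells kept in the denominator.

wt = [r.nebd_to_ao for r in records if r.condition == "WT" and r.completed]
var = [r.nebd_to_ao for r in records if r.condition == "variant" and r.completed]
stat, p = compare_groups(var, wt, test="mann_whitney")
print(f"\nNEBD->AO durations, variant vs WT: Mann-Whitney U={stat:.0f}, p={p:.2e}")
print("A delayed anaphase onset shifts t50 right and is detected by the test.")
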