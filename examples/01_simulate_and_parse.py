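"""Simulate one fraction delivery and round-trip it through log files.

Generates a small 2-field PBS plan, delivers it once under the default
machine error model, writes the record/events logs a real machine would
produce, and parses them back (strip-projection and charge-to-MU
conversion included).
"""

import tempfile
from pathlib import Path

import pbs_lfqa as q

plan = q.generate_plan(
    n_fields=2, gantry_angles=[90.0, 270.0], layers_per_field=3,
    spots_per_layer=40, target_radius=40.0, rng_seed=7,
)
geometry = q.MachineGeometry()
errors = q.ErrorModelConfig(rng_seed=1)

fraction = q.simulate_fraction(plan, geometry, errors, fraction_index=1)

with tempfile.TemporaryDirectory() as tmp:
    paths = q.write_fraction_logs(fraction, plan, geometry, tmp)
    print(f"wrote {len(paths)} log files, e.g. {Path(paths[0]).name}")
    recs = [p for p in paths if p.name.endswith(".record.csv")]
    evs = [p for p in paths if p.name.endswith(".events.jsonl")]
    parsed = q.read_fraction(recs, evs, plan, geometry, fraction_index=1)

print(f"plan spots: {plan.n_spots}, logged spots: {len(parsed.spots)}, "
      f"aborted: {parsed.aborted}")
s = parsed.spots[0]
p = plan.fields[0].layers[0].spots[0]
print(f"first spot: planned ({p.x:+.2f}, {p.y:+.2f}) mm {p.mu:.4f} MU -> "
      f"logged ({s.x_log:+.2f}, {s.y_log:+.2f}) mm {s.mu_log:.4f} MU")
print("the position difference reflects the systematic x offset at gantry "
      "90 degrees plus day-to-day noise; MU deviations are a tiny fraction "
      "of the 0.014 MU deliverable minimum.")
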