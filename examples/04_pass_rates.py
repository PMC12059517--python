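"""Spot-based pass rate Lambda(1 mm), gamma series and their correlation.

Lambda is the MU-weighted percentage of spots delivered within 1 mm of
their reference position — computable from logs alone, without dose
reconstruction.  The example evaluates every fraction against (1) the
original plan and (2) the first delivered fraction (a surrogate for a
pre-treatment QA delivery), and correlates Lambda with Gamma(1%/1 mm).
"""

import pbs_lfqa as q

plan = q.generate_plan(2, [90.0, 270.0], 3, 50, 40.0, rng_seed=7)
geometry = q.MachineGeometry()
fractions = q.simulate_course(plan, geometry,
                              q.ErrorModelConfig(rng_seed=1), 8)

for kind in ("original_plan", "first_fraction"):
    s = q.build_series(plan, fractions, reference_kind=kind,
                       criteria=q.GammaCriteria(1.0, 1.0))
    r = "undefined" if s.pearson_r is None else f"{s.pearson_r:+.2f}"
    print(f"reference = {kind}:")
    for i, (lam, gam) in enumerate(zip(s.lambda_percent, s.gamma_percent)):
        print(f"  fraction {s.fraction_indices[i]:2d}: "
              f"Lambda = {lam:5.1f}%  Gamma = {gam:5.1f}%")
    print(f"  Pearson r(Lambda, Gamma) = {r}\n")

print("against the first fraction both rates sit near 100% because the "
      "systematic machine offsets reproduce day to day; against the plan "
      "they are lower and fluctuate together, hence the positive r.")
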