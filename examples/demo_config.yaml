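# Small demonstration study: 2-field plan, 10 simulated fractions.
plan:
  plan_id: demo
  n_fields: 2
  gantry_angles: [90.0, 270.0]
  layers_per_field: 4
  spots_per_layer: 60
  target_radius: 35.0
run:
  n_fractions: 10
  seed: 42
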