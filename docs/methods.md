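# Methods

`pbs-lfqa` implements log file-based patient-specific quality assurance
(LFQA) for pencil beam scanning (PBS) proton therapy as a fully synthetic,
testable pipeline.  This note describes the models, the parameters that
matter, the numerical choices, and what the synthetic study does and does
not demonstrate about real deliveries.

## The measurement chain

A PBS machine records, for every delivered spot, the beam position measured
by strip-segmented transmission ionization chambers (ICs) in the nozzle, the
charge accumulated in the integral IC plane, and microsecond timestamps.
The package models this chain explicitly:

1. **Strip profile → centroid.**  The lateral beam profile on the position
   IC is Gaussian; the charge on strip *k* is the Gaussian probability mass
   over the strip's pitch interval.  `fit_strip_centroid` recovers the beam
   center by a least-squares Gaussian fit (amplitude, center, width),
   initialized from the charge-weighted mean and standard deviation.  The
   fit resolves the centroid far below the strip pitch; on noiseless
   profiles the round trip through `synthesize_strip_profile` recovers the
   center to better than 1 µm.  A profile whose charge maximum sits on a
   boundary strip is rejected as uncovered.

2. **IC plane → isocenter plane.**  Scanning magnets act as per-axis
   virtual sources at distances `sad_x`, `sad_y` upstream of the isocenter;
   the IC plane sits `z_ic` upstream.  Similar triangles (the intercept
   theorem) give `x_iso = x_ic · sad / (sad − z_ic)`.  The projection is
   exactly linear; the parallel-beam limit (`sad → ∞`) is the identity.

3. **Charge → MU.**  `MU = Q · k · (P_ref / P) · (T / T_ref)`: a vented
   chamber collects less charge per MU in thinner air, so the calibration
   factor `k` is corrected by the ambient pressure and temperature recorded
   at delivery time.

All positions are isocenter-plane BEV millimetres (IEC-61217: x fast-scan,
y slow-scan); timestamps are integer microseconds in files, derived times
are seconds.

## Per-spot statistics

Over the N delivered fractions of a course, each spot's parameter
(x, y, MU) gets

* accuracy `mu_s = mean_i(L_{i,s} − P_s)` — the mean deviation of logged
  from planned values,
* reproducibility `sigma_s` — the corrected (N−1) sample standard
  deviation of the logged values,
* distance accuracy — the mean over fractions of the per-fraction 2D
  Euclidean distance to plan.  By Jensen's inequality this always
  dominates `hypot(mu_x, mu_y)`; both interpretations of "distance
  accuracy" are available, the per-fraction mean is the default.

Aggregation reports, per plan and per gantry angle, the mean, the *worst*
value (largest magnitude with its sign preserved — so a table cell can read
"0.0 (−1.4)"), and a box-plot summary (linear-interpolation quartiles,
whiskers at the furthest datapoint within 1.5×IQR).  Aborted fractions are
dropped entirely from spot statistics and excluded from pass-rate and
timing analyses.  Statistics from fewer than 15 fractions trigger an
advisory warning but are computed.

## Dose engine

The dose engine is a deliberate stand-in for a treatment planning system:
an analytic pencil-beam superposition on a homogeneous water cube.  Each
spot deposits `MU · Dz(depth) · G2D(transverse offset)` along its field
axis; `Dz` is a normalized depth-dose with a quadratic build-up plateau and
a Gaussian Bragg peak (sigma `bragg_width`, default 6 mm) at the
Bragg–Kleeman range `R(E) = alpha·E^p` (defaults `alpha = 0.022 mm/MeV^p`,
`p = 1.77`, i.e. ~76 mm for 100 MeV), with a sharp Gaussian distal
falloff.  The transverse kernel is a normalized 2D Gaussian with
`sigma(z) = sigma0 + sigma_growth·z` (defaults 4 mm + 0.02/mm).  The gantry
rotates about the fixed-frame y axis; spot axes are parallel inside the
engine (scanning divergence is already handled by the log projection).

Physical fidelity is explicitly not the goal; what matters for the
pipeline — and what is tested — is that the engine is deterministic,
exactly linear in MU, translates with the spot pattern, and conserves
integral dose per MU (kernel mass escaping the default grid < 1%).  The
default grid is a 121 mm cube at 3 mm isotropic voxels centered on the
isocenter, with water starting 40 mm upstream of the isocenter.

## Gamma analysis

`gamma_index` implements the global 3D gamma: for each reference voxel
above the low-dose cutoff (default 10% of the normalization), the minimum
over evaluation sample points of
`sqrt(|r−e|²/dta² + (D_eval(e)−D_ref(r))²/delta²)` with
`delta = dose_percent/100 · normalization`.  The normalization is the
reference dose maximum, fixed once per series so fraction pass rates are
comparable; in first-fraction reference mode it is the fraction-1 dose
maximum.  A voxel passes at `gamma ≤ 1` (inclusive — the boundary case is
a pass).

Sampling follows a rectangular search lattice of step
`interp_fraction·dta` (default 10% of DTA) out to `3·dta`, with trilinear
interpolation of the evaluation dose; points outside the evaluation extent
clamp to the nearest voxel.  The lattice is processed in shells of
increasing distance with two exact pruning rules: a voxel is abandoned once
the next shell's distance term alone cannot beat its current best gamma,
and a shell is skipped for a voxel when even the most favourable dose value
inside it (bounded by min/max filters of the evaluation grid over the
shell's interpolation footprint) cannot beat the current best.  Both
bounds are rigorous, so the optimized search returns *bit-identical*
gamma values to the exhaustive dense lattice search — verified in the
tests against an independent brute-force oracle, and by running the
implementation with pruning disabled.  The cutoff applies to reference
voxels only; evaluation voxels below the cutoff may still serve as
comparison points.

## Spot-based pass rate Λ and its coupling to Γ

`Lambda_i(D) = 100 · Σ_s MU_{i,s}·[d_{i,s} < D] / Σ_s MU_{i,s}` — the
MU-weighted share of spots delivered within tolerance distance D of their
reference position, with a strict inequality (ties at `d = D` fail) and
the fraction's own logged MU in both numerator and denominator (also in
first-fraction reference mode).  Defaults pair Λ(1 mm) with Γ(1%/1 mm);
their per-plan coupling is the sample Pearson correlation.  A zero-variance
series makes the correlation undefined; it is reported as missing (`NA`),
never as 0.

Two reference choices are supported: the original plan (positions and
reconstructed plan dose) and the first delivered fraction (its logged
positions, spot-by-spot by key, and its reconstructed dose) — the latter
emulating comparison against a pre-treatment QA delivery.  Fraction 1
then scores Λ = Γ = 100% by construction and stays in the series.

## Timing analysis

Each field delivery decomposes exactly into spot drill time (per-spot
`t_end − t_start`), spot-switch time (gaps between consecutive spots
within an energy layer), energy-switch time (gaps between layers, with
layer boundaries inferred from `layer_index` changes in the record) and
interlock time (INTERLOCK_START/END event pairs).  Any portion of a drill
interval or gap covered by an interlock is re-attributed to interlock time,
so `drill + spot_switch + energy_switch + interlock` equals the field's
timestamp span to the microsecond, and excising an interlock never changes
any other component.  Delivery times exclude interlocks; beam-off time
between fields is never counted.  Reproducibility is reported as mean ±
double corrected sample standard deviation per field and per plan, plus
the percentage of interlock-free field deliveries.

## The delivery simulator and its error model

The simulator is the package's data source and defines the study
conditions.  Per spot, the logged position is the planned position plus:

* a systematic x offset `A·profile(gantry)`, default profile `−sin`,
  giving the gravity-driven signature of horizontal beams — negative
  offset at 90°, positive at 270°, zero for vertical fields
  (default A = 0.5 mm);
* a reproducible y offset per scanning row from scanning-magnet
  calibration, implemented as ± `y_row_offset` alternating with row parity
  (default 0.3 mm) — reproducible across fractions by construction;
* a per-layer, per-fraction tuning shift on y, Gaussian with sd
  `layer_tune_shift_sd` (default 0.1 mm), applied to all spots of the
  layer;
* per-spot, per-axis Gaussian day-to-day noise (default sd 0.15 mm),
  inflated by `edge_highmu_noise_multiplier` (default 2) for spots that
  are both heavy (`mu ≥ 0.1 MU`) and on the lateral field edge — defined
  as lying within one scan-line pitch of the layer's 2D convex hull.

Logged MU is planned MU plus a bias (default 0.0001 MU) and Gaussian noise
(default sd 0.0005 MU), clipped at zero but *not* re-floored at the
0.014 MU plannable minimum — a delivered spot may record slightly below it.
Timing uses a drill time proportional to delivered MU (default
100 ms/MU), Gaussian spot-switch gaps (2 ± 0.2 ms) and energy-switch gaps
(1.0 ± 0.2 s); with ~5 layers of ~100 spots this lands field delivery
times in the tens of seconds, the realistic order.  Interlocks occur per
field with probability 0.072 (so ~93% of field deliveries are clean) and
last 30 ± 10 s; the simulator inserts them into energy-switch gaps only,
while the analysis handles interlocks anywhere, including straddling a
drill interval.

Randomness uses one counter-derived substream per (fraction, field, layer)
from a single seed, so output is bit-reproducible and simulating more
fractions never perturbs earlier ones.  Ambient pressure/temperature drift
per fraction (5 hPa / 1 K sd) exercises the air-density correction; the
writer/reader round trip remains exact because both directions use the
same conversion.

The plan generator lays spots on a serpentine scan-line grid inside a
disc, draws MU from a lognormal (median 0.05 MU) truncated at the 0.014 MU
floor, and doubles the weight of convex-hull edge spots, emulating the
edge enhancement of clinically optimized plans and making the high-MU
edge-spot phenomenology reachable.

### What the synthetic study shows — and what it does not

Passing tests demonstrate that the *analysis* is correct: the statistics
match brute-force oracles exactly, gamma matches an exhaustive search,
injected error-model parameters are recovered at the configured
amplitudes, and the qualitative clinical signatures emerge (pass rates
degrade monotonically with position noise; Λ and Γ correlate strongly;
first-fraction referencing turns reproducible systematics into ~100% pass
rates).  They do not validate the error model against a particular
machine: real log files have 4 kHz intra-spot samples (pre-averaged here),
two redundant IC planes (one averaged plane here), anatomy-dependent dose
(homogeneous water here), and vendor-specific binary formats (open CSV /
JSON-lines dialects here).

## Numerical choices and degenerate inputs

* Spot matching is by `(field_id, layer_index, spot_index)` key, never by
  nearest position — deliveries preserve plan order.
* A fraction is aborted iff fewer spots were logged than planned; aborted
  fractions are excluded as described above, and `build_series` requires
  at least 3 usable fractions.
* Quartiles use the linear-interpolation convention (violin/box
  reproduction depends on it).
* Delivery-time spreads subtract the first value before computing the
  standard deviation, so identical series give exactly zero.
* `lambda_pass_rate` divides before scaling by 100 so a full pass is
  exactly 100.0.
* Gamma values beyond the search radius keep the best value found inside
  it (the distance term alone already exceeds 3 there).
* Report formatting is fixed — positions 1 decimal mm, MU 4 decimals,
  rates 1 decimal %, times 2 decimals s — to keep golden-file comparisons
  stable; undefined correlations render as `NA`.

## Problem sizes

The bundled demo study and the reproduction script use a 2-field plan of
~1000–1200 spots, 15 simulated fractions, and a 41³ dose grid at 3 mm
voxels — large enough for stable pass-rate statistics while keeping a full
run in minutes on one CPU.  All sizes are configuration, not constants.

## Known limitations

* No beam-optics or Monte Carlo transport, no CT heterogeneity, no RBE,
  no absolute dosimetry — dose is "Gy-like" arbitrary units.
* Single averaged IC plane; per-chamber redundancy checks out of scope.
* Couch rotations unsupported (gantry rotation about fixed y only).
* Local-dose gamma and ROI masks are not implemented.
* The interlock and layer-tuning magnitudes are free parameters; no public
  measurement constrains them.
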