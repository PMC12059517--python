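import numpy as np
import pytest
from scipy.optimize import curve_fit

from pbs_lfqa import (
    BeamModel,
    DoseGrid,
    build_logfile_plan,
    reconstruct_dose,
    simulate_fraction,
)
from pbs_lfqa.errors import IntegrityError, InvalidDataError
from pbs_lfqa.plans import PlanField, PlanLayer, PlanSpot, TreatmentPlan


def _scaled(plan, factor):
    return TreatmentPlan(
        plan_id="scaled",
        fields=[
            PlanField(
                field_id=f.field_id, gantry_angle=f.gantry_angle,
                layers=[
                    PlanLayer(
                        energy=l.energy,
                        spots=[PlanSpot(s.x, s.y, s.mu * factor)
                               for s in l.spots],
                    )
                    for l in f.layers
                ],
            )
            for f in plan.fields
        ],
    )


def test_dose_linear_in_mu(tiny_plan):
    d1 = reconstruct_dose(tiny_plan)
    d2 = reconstruct_dose(_scaled(tiny_plan, 2.0))
    assert np.allclose(d2.values, 2.0 * d1.values, rtol=1e-12)


def test_dose_engine_deterministic(tiny_plan):
    a = reconstruct_dose(tiny_plan)
    b = reconstruct_dose(tiny_plan)
    assert np.array_equal(a.values, b.values)


def test_single_spot_transverse_center_recovered():
    """Best-fit Gaussian center of the transverse profile equals (x, y)."""
    x0, y0 = 4.0, -6.0
    plan = TreatmentPlan(
        "one", [PlanField("F0", 0.0,
                          [PlanLayer(100.0, [PlanSpot(x0, y0, 1.0)])])]
    )
    grid = DoseGrid.empty(half_size=30.0, spacing=1.0)
    dose = reconstruct_dose(plan, grid)
    ax, ay, az = dose.axes()
    iz = int(np.unravel_index(np.argmax(dose.values), dose.shape)[2])
    profile_x = dose.values[:, np.argmin(np.abs(ay - y0)), iz]

    def g(x, a, c, w):
        return a * np.exp(-0.5 * ((x - c) / w) ** 2)

    popt, _ = curve_fit(g, ax, profile_x, p0=(profile_x.max(), 0.0, 5.0))
    assert popt[1] == pytest.approx(x0, abs=0.1)
    profile_y = dose.values[np.argmin(np.abs(ax - x0)), :, iz]
    popt, _ = curve_fit(g, ay, profile_y, p0=(profile_y.max(), 0.0, 5.0))
    assert popt[1] == pytest.approx(y0, abs=0.1)


def test_integral_dose_proportional_to_total_mu(tiny_plan):
    d1 = reconstruct_dose(tiny_plan)
    d3 = reconstruct_dose(_scaled(tiny_plan, 3.0))
    ratio = d3.values.sum() / d1.values.sum()
    assert ratio == pytest.approx(3.0, rel=1e-9)
    # kernel mass escaping the default grid is under 1% (central spot on the
    # default grid vs a much larger grid at the same spacing)
    single = TreatmentPlan(
        "c", [PlanField("F0", 0.0, [PlanLayer(97.5, [PlanSpot(0.0, 0.0, 1.0)])])]
    )
    small = reconstruct_dose(single).values.sum()
    big = reconstruct_dose(single, DoseGrid.empty(half_size=120.0,
                                                  spacing=3.0)).values.sum()
    assert small / big > 0.99


def test_translation_moves_transverse_pattern():
    """Shifting all spots by (dx, dy) shifts the dose pattern likewise."""
    base = TreatmentPlan(
        "t", [PlanField("F0", 0.0, [PlanLayer(100.0, [
            PlanSpot(0.0, 0.0, 1.0), PlanSpot(6.0, 3.0, 2.0)])])]
    )
    dx, dy = 4.0, -2.0
    moved = TreatmentPlan(
        "t2", [PlanField("F0", 0.0, [PlanLayer(100.0, [
            PlanSpot(0.0 + dx, 0.0 + dy, 1.0),
            PlanSpot(6.0 + dx, 3.0 + dy, 2.0)])])]
    )
    grid = DoseGrid.empty(half_size=40.0, spacing=1.0)
    a = reconstruct_dose(base, grid)
    b = reconstruct_dose(moved, grid)
    # with gantry 0 the transverse plane is x-y: b(x) = a(x - dx), so voxel
    # (i + sx, j + sy) of b matches voxel (i, j) of a
    sx, sy = int(dx / 1.0), int(dy / 1.0)
    interior = a.values[10:-10, 10:-10, :]
    shifted = b.values[10 + sx:interior.shape[0] + 10 + sx,
                       10 + sy:interior.shape[1] + 10 + sy, :]
    assert np.allclose(interior, shifted, atol=1e-9 * a.values.max())


def test_depth_dose_peaks_at_bragg_range():
    beam = BeamModel()
    z = np.linspace(0.0, 120.0, 4000)
    for e in (85.0, 100.0, 110.0):
        dz = beam.depth_dose(z, e)
        assert z[np.argmax(dz)] == pytest.approx(beam.range_mm(e), abs=0.2)
        assert dz.max() == pytest.approx(1.0, abs=1e-3)


def test_logfile_plan_identity_for_zero_errors(small_plan, geometry,
                                               zero_errors):
    fx = simulate_fraction(small_plan, geometry, zero_errors, 1)
    lf = build_logfile_plan(small_plan, fx)
    for (a, b) in zip(small_plan.iter_spots(), lf.iter_spots()):
        assert a[5].x == b[5].x and a[5].y == b[5].y
        assert a[5].mu == pytest.approx(b[5].mu, abs=1e-15)


def test_logfile_plan_replaces_fields(small_plan, geometry, default_errors):
    fx = simulate_fraction(small_plan, geometry, default_errors, 1)
    lf = build_logfile_plan(small_plan, fx)
    smap = fx.spot_map()
    for fid, _a, li, _e, si, s in lf.iter_spots():
        logged = smap[(fid, li, si)]
        assert s.x == logged.x_log
        assert s.y == logged.y_log
        assert s.mu == logged.mu_log


def test_logfile_plan_missing_spot_is_integrity_error(small_plan, geometry,
                                                      zero_errors):
    fx = simulate_fraction(small_plan, geometry, zero_errors, 1)
    fx.spots = fx.spots[:-1]  # lose one spot, fraction not marked aborted
    with pytest.raises(IntegrityError):
        build_logfile_plan(small_plan, fx)


def test_grid_validation():
    with pytest.raises(InvalidDataError):
        DoseGrid(np.zeros(3), np.array([1.0, 0.0, 1.0]), np.zeros((2, 2, 2)))
    with pytest.raises(InvalidDataError):
        DoseGrid(np.zeros(3), np.ones(3), -np.ones((2, 2, 2)))


def test_grid_save_load_roundtrip(tmp_path, tiny_plan):
    d = reconstruct_dose(tiny_plan)
    d.save(tmp_path / "ref")
    back = DoseGrid.load(tmp_path / "ref")
    assert back.same_frame(d)
    assert np.array_equal(back.values, d.values)
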