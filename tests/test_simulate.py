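import numpy as np
import pytest

from pbs_lfqa import (
    ErrorModelConfig,
    MachineGeometry,
    fit_strip_centroid,
    generate_plan,
    simulate_course,
    simulate_fraction,
    synthesize_strip_profile,
)
from pbs_lfqa.errors import CoverageError
from pbs_lfqa.logfile_io import strip_positions
from pbs_lfqa.plans import lateral_edge_mask


def test_zero_error_model_reproduces_plan_exactly(small_plan, geometry,
                                                  zero_errors):
    fx = simulate_fraction(small_plan, geometry, zero_errors, 1)
    smap = fx.spot_map()
    for fid, _ang, li, _e, si, s in small_plan.iter_spots():
        logged = smap[(fid, li, si)]
        assert logged.x_log == s.x
        assert logged.y_log == s.y
        assert logged.mu_log == pytest.approx(s.mu, abs=1e-15)


def test_zero_noise_timing_is_deterministic_sum(small_plan, geometry,
                                                zero_errors):
    fx = simulate_fraction(small_plan, geometry, zero_errors, 1)
    for pf in small_plan.fields:
        spots = fx.spots_of_field(pf.field_id)
        tr = fx.truth["timing"][pf.field_id]
        span = spots[-1].t_end - spots[0].t_start
        assert span == (tr["drill_us"] + tr["spot_switch_us"]
                        + tr["energy_switch_us"] + tr["interlock_us"])


def test_fixed_seed_reproduces_identical_fraction(small_plan, geometry,
                                                  default_errors):
    a = simulate_fraction(small_plan, geometry, default_errors, 3)
    b = simulate_fraction(small_plan, geometry, default_errors, 3)
    assert a.spots == b.spots
    assert a.events == b.events
    c = simulate_fraction(small_plan, geometry, default_errors, 4)
    assert a.spots != c.spots


def test_adding_fractions_never_perturbs_earlier_ones(small_plan, geometry,
                                                      default_errors):
    five = simulate_course(small_plan, geometry, default_errors, 5)
    two = simulate_course(small_plan, geometry, default_errors, 2)
    assert five[0].spots == two[0].spots
    assert five[1].spots == two[1].spots


def test_empirical_noise_sd_matches_configuration(geometry):
    """Per-spot sd over many fractions converges to the configured noise."""
    plan = generate_plan(1, [0.0], 2, 100, 40.0, rng_seed=3)
    errors = ErrorModelConfig(
        x_offset_amplitude=0.0, y_row_offset=0.0, layer_tune_shift_sd=0.0,
        position_noise_sd=0.15, edge_highmu_noise_multiplier=1.0,
        interlock_probability_per_field=0.0, rng_seed=8,
    )
    fracs = simulate_course(plan, geometry, errors, 30)
    x = np.array([[s.x_log for s in f.spots] for f in fracs])
    sd = x.std(axis=0, ddof=1)
    assert abs(sd.mean() - 0.15) / 0.15 < 0.10


def test_systematic_offsets_recovered_at_n200(geometry):
    """Empirical mean deviation converges to the injected systematics."""
    plan = generate_plan(1, [90.0], 1, 60, 40.0, rng_seed=3)
    errors = ErrorModelConfig(
        x_offset_amplitude=0.5, y_row_offset=0.0, layer_tune_shift_sd=0.0,
        position_noise_sd=0.1, edge_highmu_noise_multiplier=1.0,
        interlock_probability_per_field=0.0, rng_seed=8,
    )
    fracs = simulate_course(plan, geometry, errors, 200)
    x = np.array([[s.x_log for s in f.spots] for f in fracs])
    xp = np.array([s.x for _, _, _, _, _, s in plan.iter_spots()])
    mean_dev = (x - xp).mean()
    assert mean_dev == pytest.approx(-0.5, abs=0.5 * 0.05)
    sd = x.std(axis=0, ddof=1).mean()
    assert abs(sd - 0.1) / 0.1 < 0.05


def test_highmu_edge_spots_less_reproducible(geometry):
    plan = generate_plan(1, [0.0], 1, 120, 40.0, rng_seed=4,
                         edge_mu_boost=4.0)
    errors = ErrorModelConfig(
        x_offset_amplitude=0.0, y_row_offset=0.0, layer_tune_shift_sd=0.0,
        position_noise_sd=0.1, edge_highmu_noise_multiplier=2.5,
        highmu_threshold=0.1, interlock_probability_per_field=0.0,
        rng_seed=8,
    )
    fracs = simulate_course(plan, geometry, errors, 200)
    layer = plan.fields[0].layers[0]
    xy = np.array([[s.x, s.y] for s in layer.spots])
    mu = np.array([s.mu for s in layer.spots])
    rows = np.unique(xy[:, 1])
    edge = lateral_edge_mask(xy, float(np.median(np.diff(rows))))
    hot = edge & (mu >= errors.highmu_threshold)
    cold = ~edge & (mu < errors.highmu_threshold)
    assert hot.any() and cold.any()
    x = np.array([[s.x_log for s in f.spots] for f in fracs])
    sd = x.std(axis=0, ddof=1)
    assert sd[hot].mean() > 1.5 * sd[cold].mean()


def test_certain_interlock_probability_yields_interlock_pairs(
    small_plan, geometry
):
    errors = ErrorModelConfig(interlock_probability_per_field=1.0, rng_seed=2)
    fx = simulate_fraction(small_plan, geometry, errors, 1)
    for pf in small_plan.fields:
        kinds = [e.kind for e in fx.events_of_field(pf.field_id)]
        assert kinds.count("INTERLOCK_START") >= 1
        assert kinds.count("INTERLOCK_START") == kinds.count("INTERLOCK_END")


def test_strip_profile_mass_and_symmetry(geometry):
    q = synthesize_strip_profile(0.0, 4.0, 2.5, geometry, noise_sd=0.0)
    assert q.sum() == pytest.approx(2.5, rel=1e-9)
    assert np.argmax(q) == geometry.n_strips // 2 - (geometry.n_strips % 2 == 0)
    # symmetric about the grid center
    assert np.allclose(q, q[::-1], rtol=1e-12)


def test_strip_profile_fit_roundtrip(geometry):
    q = synthesize_strip_profile(3.2, 4.0, 1.0, geometry, noise_sd=0.0)
    c = fit_strip_centroid(q, strip_positions(geometry))
    assert c == pytest.approx(3.2, abs=1e-6)


def test_strip_profile_outside_coverage_rejected(geometry):
    x_out = geometry.n_strips / 2 * geometry.strip_pitch + 1.0
    with pytest.raises(CoverageError):
        synthesize_strip_profile(x_out, 4.0, 1.0, geometry)
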