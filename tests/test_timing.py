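import numpy as np
import pytest

from pbs_lfqa import (
    ErrorModelConfig,
    decompose_field_timing,
    decompose_fraction_timing,
    simulate_course,
    simulate_fraction,
    timing_summary,
)
from pbs_lfqa.errors import IntegrityError, InvalidDataError
from pbs_lfqa.logfile_io import Event, LoggedSpot

from _oracles import brute_corrected_sd

US = 1


def _spot(layer, idx, t0, t1):
    return LoggedSpot("F0", layer, idx, 0.0, 0.0, 0.1, t0, t1)


def _constructed_field(n_spots=100, drill_us=10_000, switch_us=2_000,
                       es_us=1_000_000, spots_per_layer=50):
    """Synthetic log: fixed drill/switch times, one energy switch."""
    spots = []
    t = 0
    for k in range(n_spots):
        layer = k // spots_per_layer
        if k > 0:
            prev_layer = (k - 1) // spots_per_layer
            t += es_us if layer != prev_layer else switch_us
        spots.append(_spot(layer, k % spots_per_layer, t, t + drill_us))
        t += drill_us
    return spots


def test_constructed_log_arithmetic():
    # 2 layers x 50 spots: 100 drills of 10 ms, 98 within-layer gaps of
    # 2 ms, one 1.0 s energy switch
    spots = _constructed_field()
    bd = decompose_field_timing(spots, [])
    assert bd.drill_total == pytest.approx(1.0)
    assert bd.spot_switch_total == pytest.approx(0.196)
    assert bd.energy_switch_total == pytest.approx(1.0)
    assert bd.interlock_total == 0.0
    assert not bd.had_interlock


def test_interlock_inside_gap_is_excised_category_neutral():
    """A 30 s interlock inside the energy-switch gap leaves the
    energy-switch total unchanged and is booked as interlock time."""
    plain = _constructed_field()
    # twin with the energy-switch gap stretched by a 30 s interlock
    stretched = []
    boundary = None
    for s in plain:
        if s.layer_index == 1 and boundary is None:
            boundary = s.t_start
        stretched.append(s)
    dur = 30_000_000
    shifted = [
        LoggedSpot(s.field_id, s.layer_index, s.spot_index, s.x_log, s.y_log,
                   s.mu_log,
                   s.t_start + (dur if s.t_start >= boundary else 0),
                   s.t_end + (dur if s.t_start >= boundary else 0))
        for s in stretched
    ]
    il_start = boundary - 500_000  # inside the original gap
    events = [Event(il_start, "INTERLOCK_START", "", "F0"),
              Event(il_start + dur, "INTERLOCK_END", "", "F0")]
    bd_plain = decompose_field_timing(plain, [])
    bd_il = decompose_field_timing(shifted, events)
    assert bd_il.energy_switch_total == pytest.approx(
        bd_plain.energy_switch_total)
    assert bd_il.drill_total == pytest.approx(bd_plain.drill_total)
    assert bd_il.spot_switch_total == pytest.approx(bd_plain.spot_switch_total)
    assert bd_il.interlock_total == pytest.approx(30.0)
    assert bd_il.had_interlock


def test_simulator_timing_matches_ground_truth(small_plan, geometry):
    errors = ErrorModelConfig(interlock_probability_per_field=0.5, rng_seed=3)
    for fi in range(1, 6):
        fx = simulate_fraction(small_plan, geometry, errors, fi)
        for bd in decompose_fraction_timing(fx):
            tr = fx.truth["timing"][bd.field_id]
            assert bd.drill_total == pytest.approx(tr["drill_us"] / 1e6,
                                                   abs=1e-6)
            assert bd.spot_switch_total == pytest.approx(
                tr["spot_switch_us"] / 1e6, abs=1e-6)
            assert bd.energy_switch_total == pytest.approx(
                tr["energy_switch_us"] / 1e6, abs=1e-6)
            assert bd.interlock_total == pytest.approx(
                tr["interlock_us"] / 1e6, abs=1e-6)


def test_component_conservation_exact(small_plan, geometry, default_errors):
    """drill + switches + interlock == last t_end - first t_start, exactly."""
    fx = simulate_fraction(small_plan, geometry, default_errors, 1)
    for fid in fx.field_ids:
        spots = fx.spots_of_field(fid)
        bd = decompose_field_timing(spots, fx.events_of_field(fid))
        span_us = spots[-1].t_end - spots[0].t_start
        total = (bd.drill_total + bd.spot_switch_total
                 + bd.energy_switch_total + bd.interlock_total)
        assert round(total * 1e6) == span_us


def test_unpaired_interlock_rejected():
    spots = _constructed_field(10, spots_per_layer=10)
    with pytest.raises(IntegrityError):
        decompose_field_timing(
            spots, [Event(5_000, "INTERLOCK_START", "", "F0")])


def test_non_monotone_events_rejected():
    spots = _constructed_field(10, spots_per_layer=10)
    events = [Event(9_000, "INTERLOCK_START", "", "F0"),
              Event(5_000, "INTERLOCK_END", "", "F0")]
    with pytest.raises((InvalidDataError, IntegrityError)):
        decompose_field_timing(spots, events)


def test_summary_identical_breakdowns_have_zero_spread():
    from pbs_lfqa.timing import TimingBreakdown

    bds = [
        TimingBreakdown("F0", i + 1, 1.0, 0.198, 1.0, 0.0, False)
        for i in range(3)
    ]
    s = timing_summary(bds)
    assert s.plan_two_sigma == 0.0
    assert s.per_field["F0"] == (pytest.approx(2.198), 0.0)
    assert s.interlock_free_percent == 100.0


def test_summary_interlock_free_ratio():
    from pbs_lfqa.timing import TimingBreakdown

    bds = [TimingBreakdown(f"F{i}", 1, 1.0, 0.1, 0.5, 0.0, i == 0)
           for i in range(14)]
    s = timing_summary(bds)
    assert s.interlock_free_percent == pytest.approx(100.0 * 13 / 14)


def test_summary_matches_bruteforce_sd():
    from pbs_lfqa.timing import TimingBreakdown

    rng = np.random.default_rng(2)
    ts = rng.uniform(30, 60, size=12)
    bds = [TimingBreakdown("F0", i + 1, t, 0.0, 0.0, 0.0, False)
           for i, t in enumerate(ts)]
    s = timing_summary(bds)
    assert s.plan_mean == pytest.approx(ts.mean(), abs=1e-12)
    assert s.plan_two_sigma == pytest.approx(2 * brute_corrected_sd(ts),
                                             abs=1e-12)
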