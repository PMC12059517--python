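"""Synthetic PBS delivery simulator.

Simulates N fraction deliveries of a treatment plan under a configurable
machine error model and produces the same record/events logs a real
delivery would, so every downstream stage (parsing, statistics, dose
reconstruction, gamma, pass rates, timing) can be exercised end-to-end.

Error model applied per spot (isocenter-plane BEV mm):

* systematic x offset ``A * profile(gantry_angle)`` — default profile
  ``-sin``, i.e. negative near 90 deg and positive near 270 deg;
* reproducible y offset per scanning row (sign alternates with row
  parity within each layer);
* per-layer, per-fraction tuning shift on y (all spots of the layer);
* per-spot, per-axis Gaussian day-to-day noise, inflated by a
  multiplier for high-MU spots on the lateral convex-hull edge of
  their layer;
* MU bias plus Gaussian noise, clipped at zero (a delivered spot may
  record slightly below the plannable minimum).

Timing: drill time proportional to delivered MU, Gaussian spot-switch
gaps within a layer, Gaussian energy-switch gaps between layers, and
optional interlocks inserted into energy-switch gaps.  Timestamps are
integer microseconds; a counter-based RNG substream per
(fraction, field, layer) makes every fraction independently
reproducible — adding fractions never perturbs earlier ones.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .errors import CoverageError, InvalidDataError
from .logfile_io import Event, FractionLog, LoggedSpot, strip_positions
from .machine import AmbientConditions, ErrorModelConfig, MachineGeometry
from .plans import PlanField, TreatmentPlan, lateral_edge_mask

_AMBIENT_STREAM = 1_000_003
_INTERLOCK_STREAM = 1_000_033

MS = 1000          # microseconds per millisecond
S = 1_000_000      # microseconds per second


def _layer_rng(seed: int, fraction: int, field_idx: int, layer_idx: int):
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(fraction, field_idx, layer_idx))
    )


def _row_offsets(y_plan: np.ndarray, amplitude: float) -> np.ndarray:
    """Reproducible per-scan-row y offset: +/- amplitude by row parity."""
    rows = np.unique(y_plan)
    idx = np.searchsorted(rows, y_plan)
    return np.where(idx % 2 == 0, amplitude, -amplitude)


def _layer_pitch(y_plan: np.ndarray) -> float:
    rows = np.unique(y_plan)
    if len(rows) < 2:
        return float("inf")
    return float(np.median(np.diff(rows)))


def simulate_fraction(
    plan: TreatmentPlan,
    geometry: MachineGeometry,
    errors: ErrorModelConfig,
    fraction_index: int,
) -> FractionLog:
    """Simulate one fraction delivery of ``plan``.

    Returns a :class:`FractionLog` whose ``truth`` dict records the injected
    systematic offsets and exact timing bookkeeping per field (integer
    microseconds) for verification against the analysis modules.
    """
    if fraction_index < 1:
        raise InvalidDataError("fraction_index must be >= 1")

    amb_rng = np.random.default_rng(
        np.random.SeedSequence(errors.rng_seed,
                               spawn_key=(fraction_index, _AMBIENT_STREAM))
    )
    ambient = AmbientConditions(
        pressure=float(geometry.ref_pressure
                       + errors.pressure_sd * amb_rng.standard_normal()),
        temperature=float(geometry.ref_temperature
                          + errors.temperature_sd * amb_rng.standard_normal()),
    )

    spots: list[LoggedSpot] = []
    events: list[Event] = []
    truth_timing: dict[str, dict[str, int]] = {}
    truth_sys: dict[str, dict] = {}

    t = 0  # fraction clock, us; inter-field beam-off time is not modelled
    for field_idx, pf in enumerate(plan.fields):
        t, field_spots, field_events, timing, sysinfo = _simulate_field(
            pf, field_idx, geometry, errors, fraction_index, t
        )
        spots.extend(field_spots)
        events.extend(field_events)
        truth_timing[pf.field_id] = timing
        truth_sys[pf.field_id] = sysinfo
        t += 60 * S  # gantry rotation / beam-off between fields (never analysed)

    return FractionLog(
        fraction_index=fraction_index,
        spots=spots,
        events=events,
        aborted=False,
        ambient=ambient,
        truth={"timing": truth_timing, "systematic": truth_sys},
    )


def _simulate_field(
    pf: PlanField,
    field_idx: int,
    geometry: MachineGeometry,
    errors: ErrorModelConfig,
    fraction_index: int,
    t0: int,
):
    sys_x = errors.systematic_x_offset(pf.gantry_angle)
    field_spots: list[LoggedSpot] = []
    events: list[Event] = [Event(t0, "FIELD_START", pf.field_id, pf.field_id)]
    drill_total = 0
    ss_total = 0
    es_total = 0

    t = t0
    es_gap_bounds: list[tuple[int, int]] = []  # energy-switch intervals
    layer_shifts: list[float] = []
    for layer_idx, layer in enumerate(pf.layers):
        rng = _layer_rng(errors.rng_seed, fraction_index, field_idx, layer_idx)
        n = len(layer.spots)
        x_plan = np.array([s.x for s in layer.spots])
        y_plan = np.array([s.y for s in layer.spots])
        mu_plan = np.array([s.mu for s in layer.spots])

        tune = errors.layer_tune_shift_sd * rng.standard_normal()
        layer_shifts.append(float(tune))
        mult = np.ones(n)
        if errors.edge_highmu_noise_multiplier > 1.0:
            edge = lateral_edge_mask(
                np.column_stack([x_plan, y_plan]), _layer_pitch(y_plan)
            )
            mult = np.where(
                edge & (mu_plan >= errors.highmu_threshold),
                errors.edge_highmu_noise_multiplier, 1.0,
            )
        noise = rng.standard_normal((2, n)) * errors.position_noise_sd * mult
        x_log = x_plan + sys_x + noise[0]
        y_log = y_plan + _row_offsets(y_plan, errors.y_row_offset) + tune + noise[1]
        mu_log = np.maximum(
            mu_plan + errors.mu_bias + errors.mu_noise_sd * rng.standard_normal(n),
            0.0,
        )

        ss_mean, ss_sd = errors.spot_switch_time
        switch_us = np.maximum(
            np.rint((ss_mean + ss_sd * rng.standard_normal(n)) * MS), 0
        ).astype(int)

        if layer_idx > 0:
            es_mean, es_sd = errors.energy_switch_time
            gap = max(int(round((es_mean + es_sd * rng.standard_normal()) * S)), 0)
            es_gap_bounds.append((t, t + gap))
            es_total += gap
            t += gap
        events.append(Event(t, "LAYER_START", f"layer={layer_idx}", pf.field_id))

        for k in range(n):
            drill = max(int(round(errors.drill_time_per_mu * mu_log[k] * MS)), 0)
            t_start = t
            t_end = t + drill
            drill_total += drill
            field_spots.append(
                LoggedSpot(pf.field_id, layer_idx, k,
                           float(x_log[k]), float(y_log[k]), float(mu_log[k]),
                           t_start, t_end)
            )
            t = t_end
            if k < n - 1:
                ss_total += int(switch_us[k])
                t += int(switch_us[k])
        events.append(Event(t, "LAYER_END", f"layer={layer_idx}", pf.field_id))

    # interlocks: inserted into an energy-switch gap, shifting all later times
    il_total = 0
    il_rng = np.random.default_rng(
        np.random.SeedSequence(errors.rng_seed,
                               spawn_key=(fraction_index, field_idx,
                                          _INTERLOCK_STREAM))
    )
    if (
        es_gap_bounds
        and il_rng.random() < errors.interlock_probability_per_field
    ):
        gap_start, gap_end = es_gap_bounds[
            int(il_rng.integers(len(es_gap_bounds)))
        ]
        d_mean, d_sd = errors.interlock_duration
        dur = max(int(round((d_mean + d_sd * il_rng.standard_normal()) * S)), S)
        il_at = gap_start + (gap_end - gap_start) // 2
        field_spots = [
            LoggedSpot(s.field_id, s.layer_index, s.spot_index,
                       s.x_log, s.y_log, s.mu_log,
                       s.t_start + (dur if s.t_start >= il_at else 0),
                       s.t_end + (dur if s.t_start >= il_at else 0))
            for s in field_spots
        ]
        events = [
            Event(e.timestamp + (dur if e.timestamp >= il_at else 0),
                  e.kind, e.payload, e.field_id)
            for e in events
        ]
        events.append(Event(il_at, "INTERLOCK_START", "beam interrupted",
                            pf.field_id))
        events.append(Event(il_at + dur, "INTERLOCK_END", "beam resumed",
                            pf.field_id))
        il_total = dur
        t += dur

    events.append(Event(t, "FIELD_END", pf.field_id, pf.field_id))
    events.sort(key=lambda e: (e.timestamp, e.kind != "INTERLOCK_START"))
    timing = {
        "drill_us": drill_total,
        "spot_switch_us": ss_total,
        "energy_switch_us": es_total,
        "interlock_us": il_total,
    }
    sysinfo = {
        "x_offset": sys_x,
        "layer_tune_shifts": layer_shifts,
        "y_row_offset": errors.y_row_offset,
    }
    return t, field_spots, events, timing, sysinfo


def simulate_course(
    plan: TreatmentPlan,
    geometry: MachineGeometry,
    errors: ErrorModelConfig,
    n_fractions: int,
) -> list[FractionLog]:
    """Simulate ``n_fractions`` independent fraction deliveries."""
    if n_fractions < 1:
        raise InvalidDataError("n_fractions must be >= 1")
    return [
        simulate_fraction(plan, geometry, errors, i + 1)
        for i in range(n_fractions)
    ]


def synthesize_strip_profile(
    x_true_ic: float,
    beam_sigma_ic: float,
    total_charge: float,
    geometry: MachineGeometry,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-strip charges of a Gaussian beam on the strip-segmented IC.

    Charge on strip k is the Gaussian probability mass over the strip's
    pitch interval times ``total_charge``, plus optional additive noise.
    The beam core (±3 sigma) must lie within the instrumented range.
    """
    if beam_sigma_ic <= 0:
        raise InvalidDataError("beam sigma must be positive")
    centers = strip_positions(geometry)
    half = geometry.strip_pitch / 2.0
    lo_edge = centers[0] - half
    hi_edge = centers[-1] + half
    if x_true_ic - 3 * beam_sigma_ic < lo_edge or x_true_ic + 3 * beam_sigma_ic > hi_edge:
        raise CoverageError("beam core extends beyond strip coverage")

    z_hi = (centers + half - x_true_ic) / (beam_sigma_ic * math.sqrt(2))
    z_lo = (centers - half - x_true_ic) / (beam_sigma_ic * math.sqrt(2))
    from scipy.special import erf

    mass = 0.5 * (erf(z_hi) - erf(z_lo))
    charges = total_charge * mass
    if noise_sd > 0:
        gen = rng if rng is not None else np.random.default_rng()
        charges = charges + noise_sd * gen.standard_normal(len(charges))
    return charges
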