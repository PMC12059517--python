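"""Machine geometry, ambient conditions and the delivery error model.

The nozzle houses strip-segmented transmission ionization chambers (ICs)
upstream of the isocenter; logged spot positions are measured at the IC
plane and projected into the isocenter plane by similar triangles from a
per-axis virtual scanning source (intercept theorem).  The error model
parameterizes the machine behaviour observed in clinical PBS deliveries:
gantry-angle-dependent systematic x offsets (worst near horizontal
beams), reproducible scanning-row offsets in y, per-layer tuning shifts,
small day-to-day per-spot position noise, reduced reproducibility of
high-MU field-edge spots, near-zero MU deviations, and reproducible
drill/spot-switch/energy-switch timing with occasional interlocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import GeometryError, InvalidDataError


@dataclass(frozen=True)
class AmbientConditions:
    """Air pressure (hPa) and temperature (K) at delivery time."""

    pressure: float = 1013.25
    temperature: float = 293.15

    def __post_init__(self) -> None:
        if self.pressure <= 0 or self.temperature <= 0:
            raise InvalidDataError("pressure and temperature must be positive")


@dataclass(frozen=True)
class MachineGeometry:
    """Scanning geometry of the nozzle.

    Parameters
    ----------
    sad_x, sad_y
        Virtual source-to-axis distance per scanning axis, mm.  The x and y
        scanning magnets sit at different distances, hence per-axis SADs.
    z_ic
        Distance of the (averaged) IC measurement plane upstream of the
        isocenter, mm.
    strip_pitch, n_strips
        Strip segmentation of the position-sensitive IC.
    calibration_factor
        Machine-specific conversion, MU per unit accumulated charge at
        reference air density.
    ref_pressure, ref_temperature
        Reference conditions of the calibration (hPa, K).
    """

    sad_x: float = 2300.0
    sad_y: float = 1800.0
    z_ic: float = 450.0
    strip_pitch: float = 2.0
    n_strips: int = 64
    calibration_factor: float = 3.0
    ref_pressure: float = 1013.25
    ref_temperature: float = 293.15

    def __post_init__(self) -> None:
        if not (self.sad_x > self.z_ic > 0 and self.sad_y > self.z_ic):
            raise GeometryError("require sad_x, sad_y > z_ic > 0")
        if self.n_strips < 5:
            raise GeometryError("need at least 5 strips for a Gaussian fit")
        if self.strip_pitch <= 0 or self.calibration_factor <= 0:
            raise GeometryError("strip pitch and calibration factor must be positive")

    def projection_factor(self, axis: str) -> float:
        """Isocenter-plane magnification sad / (sad - z_ic) for ``axis``."""
        sad = {"x": self.sad_x, "y": self.sad_y}.get(axis)
        if sad is None:
            raise InvalidDataError(f"axis must be 'x' or 'y', got {axis!r}")
        return sad / (sad - self.z_ic)


def x_offset_sin_profile(gantry_angle_deg: float) -> float:
    """Default angular profile of the systematic x offset (unit amplitude).

    Returns -sin(angle): negative at 90 deg, positive at 270 deg, zero for
    vertical beams — the gravity-driven signature of horizontal deliveries.
    """
    return -math.sin(math.radians(gantry_angle_deg))


_X_PROFILES = {"sin": x_offset_sin_profile, "none": lambda a: 0.0}


@dataclass(frozen=True)
class ErrorModelConfig:
    """Configurable machine error model for the delivery simulator.

    All position amplitudes in mm, MU terms in MU, timing in the stated
    unit.  ``rng_seed`` plus the full config determine the output
    bit-exactly; fractions use independent counter-derived substreams.
    """

    # systematic position errors
    x_offset_amplitude: float = 0.5
    x_offset_angle_profile: str = "sin"
    y_row_offset: float = 0.3
    layer_tune_shift_sd: float = 0.1
    # stochastic position errors
    position_noise_sd: float = 0.15
    edge_highmu_noise_multiplier: float = 2.0
    highmu_threshold: float = 0.1
    # MU errors
    mu_noise_sd: float = 0.0005
    mu_bias: float = 0.0001
    # timing (drill time proportional to delivered MU)
    drill_time_per_mu: float = 100.0        # ms / MU
    spot_switch_time: tuple[float, float] = (2.0, 0.2)     # ms (mean, sd)
    energy_switch_time: tuple[float, float] = (1.0, 0.2)   # s (mean, sd)
    # interlocks
    interlock_probability_per_field: float = 0.072
    interlock_duration: tuple[float, float] = (30.0, 10.0)  # s (mean, sd)
    # ambient drift between fractions (hPa, K standard deviations)
    pressure_sd: float = 5.0
    temperature_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("layer_tune_shift_sd", "position_noise_sd", "mu_noise_sd",
                     "pressure_sd", "temperature_sd"):
            if getattr(self, name) < 0:
                raise InvalidDataError(f"{name} must be >= 0")
        if self.edge_highmu_noise_multiplier < 1:
            raise InvalidDataError("edge_highmu_noise_multiplier must be >= 1")
        if not 0.0 <= self.interlock_probability_per_field <= 1.0:
            raise InvalidDataError("interlock probability must lie in [0, 1]")
        if self.x_offset_angle_profile not in _X_PROFILES:
            raise InvalidDataError(
                f"unknown x offset profile {self.x_offset_angle_profile!r}; "
                f"choose from {sorted(_X_PROFILES)}"
            )
        for pair in (self.spot_switch_time, self.energy_switch_time,
                     self.interlock_duration):
            if pair[1] < 0:
                raise InvalidDataError("timing standard deviations must be >= 0")

    def systematic_x_offset(self, gantry_angle_deg: float) -> float:
        """Systematic x offset (mm) at the given gantry angle."""
        return self.x_offset_amplitude * _X_PROFILES[self.x_offset_angle_profile](
            gantry_angle_deg
        )

    @classmethod
    def zero(cls, rng_seed: int = 0) -> "ErrorModelConfig":
        """An error-free machine: logs reproduce the plan bit-exactly."""
        return cls(
            x_offset_amplitude=0.0, y_row_offset=0.0, layer_tune_shift_sd=0.0,
            position_noise_sd=0.0, edge_highmu_noise_multiplier=1.0,
            mu_noise_sd=0.0, mu_bias=0.0,
            spot_switch_time=(2.0, 0.0), energy_switch_time=(1.0, 0.0),
            interlock_probability_per_field=0.0,
            pressure_sd=0.0, temperature_sd=0.0, rng_seed=rng_seed,
        )
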