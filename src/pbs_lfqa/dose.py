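"""Analytic pencil-beam dose engine on a homogeneous water volume.

This is a deliberately simple superposition engine: each spot deposits a
normalized depth-dose curve with a Bragg-like peak along its field axis
times a normalized 2D Gaussian in the transverse plane.  Its purpose is
to propagate spot position/MU perturbations into a 3D dose distribution
with realistic sensitivity — not to model proton transport physics
(no heterogeneity, no nuclear halo, no CT).

Geometry: the isocenter sits at the world origin; the gantry rotates
about the fixed-frame y axis (IEC); at gantry 0 the beam travels along
-z.  The BEV fast-scan x axis rotates with the gantry, the slow-scan y
axis is the fixed y axis.  Water starts ``entry_depth`` mm upstream of
the isocenter along each field axis; spot axes are parallel (scanning
divergence is handled upstream, in the log projection).

The depth dose is D(z) = plateau + Gaussian Bragg peak at the
Bragg-Kleeman range R(E) = alpha * E^p, normalized to 1 at the peak,
with a sharp Gaussian distal falloff.  The engine is deterministic and
exactly linear in every spot's MU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import GeometryError, IntegrityError, InvalidDataError
from .logfile_io import FractionLog
from .plans import PlanField, PlanLayer, PlanSpot, TreatmentPlan


@dataclass
class DoseGrid:
    """3D scalar dose on a regular grid (mm origin/spacing, fixed frame)."""

    origin: np.ndarray      # (3,) mm, center of voxel [0,0,0]
    spacing: np.ndarray     # (3,) mm
    values: np.ndarray      # (nx, ny, nz)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.origin.shape != (3,) or self.spacing.shape != (3,):
            raise InvalidDataError("origin and spacing must be 3-vectors")
        if np.any(self.spacing <= 0):
            raise InvalidDataError("grid spacing must be positive")
        if self.values.ndim != 3:
            raise InvalidDataError("dose values must be a 3D array")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise InvalidDataError("dose values must be finite and >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers along each axis."""
        return tuple(
            self.origin[k] + self.spacing[k] * np.arange(self.shape[k])
            for k in range(3)
        )  # type: ignore[return-value]

    def same_frame(self, other: "DoseGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
        )

    @classmethod
    def empty(
        cls,
        half_size: float = 60.0,
        spacing: float = 3.0,
    ) -> "DoseGrid":
        """Cubic water grid centered on the isocenter (default 3 mm voxels)."""
        n = int(round(2 * half_size / spacing)) + 1
        origin = np.full(3, -half_size)
        return cls(origin, np.full(3, spacing), np.zeros((n, n, n)))

    # ------------------------------------------------------------------ io

    def save(self, path_stem: str | Path) -> tuple[Path, Path]:
        """Persist as ``<stem>.npy`` plus a ``<stem>.json`` sidecar."""
        stem = Path(path_stem)
        npy = stem.with_suffix(".npy")
        meta = stem.with_suffix(".json")
        np.save(npy, self.values)
        meta.write_text(json.dumps({
            "origin_mm": self.origin.tolist(),
            "spacing_mm": self.spacing.tolist(),
            "shape": list(self.shape),
        }, indent=1))
        return npy, meta

    @classmethod
    def load(cls, path_stem: str | Path) -> "DoseGrid":
        stem = Path(path_stem)
        meta = json.loads(stem.with_suffix(".json").read_text())
        values = np.load(stem.with_suffix(".npy"))
        return cls(np.array(meta["origin_mm"]), np.array(meta["spacing_mm"]),
                   values)


@dataclass(frozen=True)
class BeamModel:
    """Parameters of the analytic pencil-beam kernel.

    range:      R(E) = alpha * E^p  (mm, E in MeV; defaults follow the
                Bragg-Kleeman rule for water)
    bragg_width: Gaussian sigma of the Bragg peak along depth, mm
    sigma0:      lateral Gaussian sigma at the water surface, mm
    sigma_growth: lateral sigma increase per mm depth (scattering)
    """

    alpha: float = 0.022
    p: float = 1.77
    bragg_width: float = 6.0
    sigma0: float = 4.0
    sigma_growth: float = 0.02

    def __post_init__(self) -> None:
        if min(self.alpha, self.p, self.bragg_width, self.sigma0) <= 0:
            raise InvalidDataError("beam model parameters must be positive")
        if self.sigma_growth < 0:
            raise InvalidDataError("sigma_growth must be >= 0")

    def range_mm(self, energy_mev: float) -> float:
        return self.alpha * energy_mev ** self.p

    def depth_dose(self, depth: np.ndarray, energy_mev: float) -> np.ndarray:
        """Normalized depth-dose: quadratic build-up plateau + Bragg peak."""
        R = self.range_mm(energy_mev)
        w = self.bragg_width
        z = np.asarray(depth, dtype=float)
        out = np.zeros_like(z)
        prox = (z >= 0) & (z <= R)
        out[prox] = 0.25 + 0.35 * (z[prox] / R) ** 2 \
            + 0.4 * np.exp(-0.5 * ((z[prox] - R) / w) ** 2)
        distal = z > R
        out[distal] = np.exp(-0.5 * ((z[distal] - R) / (0.6 * w)) ** 2)
        return out

    def sigma(self, depth: np.ndarray) -> np.ndarray:
        return self.sigma0 + self.sigma_growth * np.clip(depth, 0.0, None)


def reconstruct_dose(
    plan: TreatmentPlan,
    grid: DoseGrid | None = None,
    beam: BeamModel | None = None,
    entry_depth: float = 40.0,
    *,
    transverse_cut_sigmas: float = 4.0,
) -> DoseGrid:
    """Superpose pencil-beam kernels for every spot of ``plan`` onto ``grid``.

    dose(v) = sum_spots MU * Dz(depth along field axis) * G2D(transverse
    offset from the spot center), with the transverse Gaussian normalized
    so that integral dose is proportional to total MU.  A spot whose
    kernel misses the grid entirely is skipped and counted in the result's
    ``n_skipped_spots`` attribute; a :class:`GeometryError` is raised only
    when no spot at all deposits dose inside the grid.
    """
    grid = DoseGrid(grid.origin, grid.spacing, np.zeros(grid.shape)) \
        if grid is not None else DoseGrid.empty()
    beam = beam or BeamModel()

    ax, ay, az = grid.axes()
    X, Y, Z = np.meshgrid(ax, ay, az, indexing="ij")
    dose = np.zeros(grid.shape)

    n_skipped = 0
    n_total = 0
    for pf in plan.fields:
        theta = np.deg2rad(pf.gantry_angle)
        # beam direction and BEV transverse axes in the fixed frame
        u = np.array([np.sin(theta), 0.0, -np.cos(theta)])
        ex = np.array([np.cos(theta), 0.0, np.sin(theta)])
        depth = X * u[0] + Z * u[2] + entry_depth
        tx = X * ex[0] + Z * ex[2]
        ty = Y
        for layer in pf.layers:
            dz = beam.depth_dose(depth, layer.energy)
            sig = beam.sigma(depth)
            idx = np.nonzero(dz > 1e-6)
            if idx[0].size == 0:
                n_skipped += len(layer.spots)
                n_total += len(layer.spots)
                continue
            dz_act = dz[idx]
            sig_act = sig[idx]
            tx_act = tx[idx]
            ty_act = ty[idx]
            norm = 1.0 / (2.0 * np.pi * sig_act ** 2)
            cut = transverse_cut_sigmas
            for s in layer.spots:
                n_total += 1
                r2 = (tx_act - s.x) ** 2 + (ty_act - s.y) ** 2
                m = r2 <= (cut * sig_act) ** 2
                if not m.any():
                    n_skipped += 1
                    continue
                contrib = s.mu * dz_act[m] * norm[m] * np.exp(
                    -0.5 * r2[m] / sig_act[m] ** 2
                )
                dose[idx[0][m], idx[1][m], idx[2][m]] += contrib
    if n_total > 0 and n_skipped == n_total:
        raise GeometryError("no spot deposits dose inside the grid")
    grid.values = dose
    grid.n_skipped_spots = n_skipped  # type: ignore[attr-defined]
    return grid


def build_logfile_plan(plan: TreatmentPlan, fraction: FractionLog) -> TreatmentPlan:
    """Overwrite planned spot x/y/MU with the fraction's logged values.

    Energies and gantry angles are untouched.  For a non-aborted fraction
    every planned spot must be present in the log; aborted fractions yield
    a partial plan containing only the delivered spots.
    """
    smap = fraction.spot_map()
    fields = []
    for pf in plan.fields:
        layers = []
        for li, layer in enumerate(pf.layers):
            spots = []
            for si, s in enumerate(layer.spots):
                key = (pf.field_id, li, si)
                logged = smap.get(key)
                if logged is None:
                    if not fraction.aborted:
                        raise IntegrityError(
                            f"spot {key} missing from non-aborted fraction "
                            f"{fraction.fraction_index}"
                        )
                    continue
                spots.append(_unchecked_spot(logged.x_log, logged.y_log,
                                             logged.mu_log))
            if spots:
                layers.append(PlanLayer(energy=layer.energy, spots=spots))
        if layers:
            fields.append(PlanField(field_id=pf.field_id,
                                    gantry_angle=pf.gantry_angle,
                                    layers=layers))
    return TreatmentPlan(
        plan_id=f"{plan.plan_id}+fx{fraction.fraction_index}", fields=fields
    )


def _unchecked_spot(x: float, y: float, mu: float) -> PlanSpot:
    # logged MU may legitimately fall below the plannable minimum, so bypass
    # the PlanSpot floor check
    s = PlanSpot.__new__(PlanSpot)
    object.__setattr__(s, "x", x)
    object.__setattr__(s, "y", y)
    object.__setattr__(s, "mu", mu)
    return s
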