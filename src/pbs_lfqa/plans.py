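"""Treatment plans for pencil beam scanning: spot lists and plan generation.

A PBS treatment plan is a hierarchy of fields (one gantry angle each),
energy layers (one beam energy each) and spots.  Spot lateral positions
are given in the IEC-61217 beam's eye view (BEV) frame at the isocenter
plane: ``x`` is the fast-scanning axis, ``y`` the slow-scanning axis,
both in mm.  Spot weights are monitor units (MU).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from .errors import InvalidDataError

#: Minimum deliverable single-spot monitor units of the modelled machine.
MIN_SPOT_MU = 0.014


@dataclass(frozen=True)
class PlanSpot:
    """One planned spot: BEV position (mm) and weight (MU)."""

    x: float
    y: float
    mu: float

    def __post_init__(self) -> None:
        if self.mu < MIN_SPOT_MU:
            raise InvalidDataError(
                f"planned spot MU {self.mu} below deliverable minimum {MIN_SPOT_MU}"
            )


@dataclass
class PlanLayer:
    """All spots delivered at one beam energy (MeV)."""

    energy: float
    spots: list[PlanSpot]

    def __post_init__(self) -> None:
        if self.energy <= 0:
            raise InvalidDataError("layer energy must be positive")
        if not self.spots:
            raise InvalidDataError("layer must contain at least one spot")


@dataclass
class PlanField:
    """One treatment field: fixed gantry angle, ordered energy layers."""

    field_id: str
    gantry_angle: float
    layers: list[PlanLayer]

    def __post_init__(self) -> None:
        if not 0.0 <= self.gantry_angle < 360.0:
            raise InvalidDataError("gantry angle must lie in [0, 360)")
        if not self.layers:
            raise InvalidDataError("field must contain at least one layer")

    @property
    def n_spots(self) -> int:
        return sum(len(layer.spots) for layer in self.layers)


@dataclass
class TreatmentPlan:
    """A full PBS plan: ordered fields of ordered energy layers of spots."""

    plan_id: str
    fields: list[PlanField] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.fields:
            raise InvalidDataError("plan must contain at least one field")
        if self.n_spots == 0:
            raise InvalidDataError("plan must contain at least one spot")

    @property
    def n_spots(self) -> int:
        return sum(f.n_spots for f in self.fields)

    def iter_spots(self) -> Iterator[tuple[str, float, int, float, int, PlanSpot]]:
        """Yield ``(field_id, gantry_angle, layer_index, energy, spot_index, spot)``."""
        for f in self.fields:
            for li, layer in enumerate(f.layers):
                for si, spot in enumerate(layer.spots):
                    yield f.field_id, f.gantry_angle, li, layer.energy, si, spot

    def spot_table(self) -> "np.recarray":
        """Flat structured array of all spots (used by the dose engine)."""
        rows = [
            (fid, ang, li, e, si, s.x, s.y, s.mu)
            for fid, ang, li, e, si, s in self.iter_spots()
        ]
        return np.rec.fromrecords(
            rows,
            names="field_id,gantry_angle,layer_index,energy,spot_index,x,y,mu",
        )

    # ------------------------------------------------------------------ io

    def to_dict(self) -> dict:
        return {
            "plan_id": self.plan_id,
            "fields": [
                {
                    "field_id": f.field_id,
                    "gantry_angle": f.gantry_angle,
                    "layers": [
                        {
                            "energy_mev": layer.energy,
                            "spots": [
                                {"x_mm": s.x, "y_mm": s.y, "mu": s.mu}
                                for s in layer.spots
                            ],
                        }
                        for layer in f.layers
                    ],
                }
                for f in self.fields
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreatmentPlan":
        return cls(
            plan_id=d["plan_id"],
            fields=[
                PlanField(
                    field_id=fd["field_id"],
                    gantry_angle=float(fd["gantry_angle"]),
                    layers=[
                        PlanLayer(
                            energy=float(ld["energy_mev"]),
                            spots=[
                                PlanSpot(float(s["x_mm"]), float(s["y_mm"]), float(s["mu"]))
                                for s in ld["spots"]
                            ],
                        )
                        for ld in fd["layers"]
                    ],
                )
                for fd in d["fields"]
            ],
        )

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load_json(cls, path: str | Path) -> "TreatmentPlan":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def save_csv(self, path: str | Path) -> None:
        """Flat one-row-per-spot export."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                ["field_id", "gantry_angle", "layer_index", "energy_mev",
                 "spot_index", "x_mm", "y_mm", "mu"]
            )
            for fid, ang, li, e, si, s in self.iter_spots():
                w.writerow([fid, repr(ang), li, repr(e), si, repr(s.x), repr(s.y), repr(s.mu)])


# ---------------------------------------------------------------------------
# Plan generation


def lateral_edge_mask(xy: np.ndarray, pitch: float) -> np.ndarray:
    """Mark spots within one scan-line pitch of the layer's 2D convex hull.

    This is the operational definition of "lateral field edge" used both by
    the plan generator (edge MU enhancement) and the delivery simulator
    (reduced reproducibility of heavy edge spots).  Degenerate layers
    (fewer than 3 distinct points, or collinear) are treated as all-edge.
    """
    from scipy.spatial import ConvexHull, QhullError

    n = len(xy)
    if n < 4:
        return np.ones(n, dtype=bool)
    try:
        hull = ConvexHull(xy)
    except QhullError:
        return np.ones(n, dtype=bool)
    verts = xy[hull.vertices]
    # distance of every point to each hull edge segment
    dmin = np.full(n, np.inf)
    for i in range(len(verts)):
        a = verts[i]
        b = verts[(i + 1) % len(verts)]
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            d = np.linalg.norm(xy - a, axis=1)
        else:
            t = np.clip((xy - a) @ ab / denom, 0.0, 1.0)
            proj = a + t[:, None] * ab
            d = np.linalg.norm(xy - proj, axis=1)
        dmin = np.minimum(dmin, d)
    return dmin <= pitch


def _scanline_grid(target_radius: float, n_spots: int) -> tuple[np.ndarray, float]:
    """Regular serpentine scan-line grid of exactly ``n_spots`` inside a disc."""
    if n_spots == 1:
        return np.zeros((1, 2)), target_radius
    # start from the equal-area pitch and shrink until enough points fit
    pitch = float(np.sqrt(np.pi * target_radius**2 / n_spots))
    for _ in range(60):
        k = int(np.ceil(target_radius / pitch))
        ax = np.arange(-k, k + 1) * pitch
        gx, gy = np.meshgrid(ax, ax)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        inside = pts[np.hypot(pts[:, 0], pts[:, 1]) <= target_radius]
        if len(inside) >= n_spots:
            break
        pitch *= 0.95
    else:  # pragma: no cover - geometric construction always terminates
        raise InvalidDataError("could not place requested spot count in target disc")
    # keep the n closest to the axis, then order as serpentine scan lines
    order = np.argsort(np.hypot(inside[:, 0], inside[:, 1]), kind="stable")
    sel = inside[order[:n_spots]]
    rows = np.round(sel[:, 1] / pitch).astype(int)
    key = np.lexsort((np.where(rows % 2 == 0, sel[:, 0], -sel[:, 0]), rows))
    return sel[key], pitch


def generate_plan(
    n_fields: int,
    gantry_angles: list[float],
    layers_per_field: int,
    spots_per_layer: int,
    target_radius: float,
    rng_seed: int,
    *,
    energy_range: tuple[float, float] = (85.0, 110.0),
    median_spot_mu: float = 0.05,
    mu_log_sigma: float = 0.6,
    edge_mu_boost: float = 2.0,
    plan_id: str = "synthetic",
) -> TreatmentPlan:
    """Generate a synthetic PBS plan.

    Spots lie on a regular serpentine scan-line grid inside a disc of
    ``target_radius`` mm; each field re-uses the same grid (a realistic PBS
    plan repaints near-identical spot maps per layer).  Spot MU is drawn from
    a lognormal distribution (median ``median_spot_mu``) truncated at the
    machine minimum of 0.014 MU, with convex-hull edge spots boosted by
    ``edge_mu_boost`` to emulate the field-edge weight enhancement of
    clinically optimized plans.  Deterministic for a fixed seed.
    """
    if n_fields < 1 or layers_per_field < 1 or spots_per_layer < 1:
        raise InvalidDataError("all counts must be >= 1")
    if len(gantry_angles) != n_fields:
        raise InvalidDataError("need one gantry angle per field")
    for a in gantry_angles:
        if not 0.0 <= a < 360.0:
            raise InvalidDataError(f"gantry angle {a} outside [0, 360)")
    if target_radius <= 0:
        raise InvalidDataError("target radius must be positive")

    xy, pitch = _scanline_grid(target_radius, spots_per_layer)
    edge = lateral_edge_mask(xy, pitch)
    e_lo, e_hi = energy_range
    if layers_per_field == 1:
        energies = [0.5 * (e_lo + e_hi)]
    else:
        energies = list(np.linspace(e_lo, e_hi, layers_per_field))

    fields = []
    for fi in range(n_fields):
        layers = []
        for li in range(layers_per_field):
            rng = np.random.default_rng(
                np.random.SeedSequence(rng_seed, spawn_key=(fi, li))
            )
            mu = rng.lognormal(mean=np.log(median_spot_mu), sigma=mu_log_sigma,
                               size=spots_per_layer)
            mu = np.where(edge, mu * edge_mu_boost, mu)
            mu = np.maximum(mu, MIN_SPOT_MU)
            layers.append(
                PlanLayer(
                    energy=energies[li],
                    spots=[
                        PlanSpot(float(x), float(y), float(m))
                        for (x, y), m in zip(xy, mu)
                    ],
                )
            )
        fields.append(
            PlanField(field_id=f"F{fi}", gantry_angle=float(gantry_angles[fi]),
                      layers=layers)
        )
    return TreatmentPlan(plan_id=plan_id, fields=fields)
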