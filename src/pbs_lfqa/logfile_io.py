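"""Reading and writing delivery log files.

Two per-field, per-fraction files make up one delivery record:

* the **record** file (CSV): one row per delivered spot with the IC-plane
  position average, accumulated charge and start/end timestamps.  Header
  comment lines (``# key=value``) carry field id, gantry angle, ambient
  pressure/temperature and the MU calibration factor.
* the **events** file (JSON lines): time-resolved status messages —
  field/layer markers, warnings and interlock start/end pairs.

Reading a fraction reconstructs isocenter-plane BEV positions via the
intercept theorem and converts accumulated charge to MU with the
machine calibration factor and the conventional air-density correction.
Timestamps are integer microseconds throughout; derived times are
reported in seconds elsewhere.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .errors import (
    CoverageError,
    FormatError,
    GeometryError,
    IntegrityError,
    InvalidDataError,
)
from .machine import AmbientConditions, MachineGeometry
from .plans import TreatmentPlan

EVENT_KINDS = frozenset(
    {"FIELD_START", "FIELD_END", "LAYER_START", "LAYER_END",
     "INTERLOCK_START", "INTERLOCK_END", "WARNING"}
)

RECORD_COLUMNS_IC = ["layer_index", "energy_mev", "spot_index",
                     "x_ic_mm", "y_ic_mm", "charge", "t_start_us", "t_end_us"]
RECORD_COLUMNS_ISO = ["layer_index", "energy_mev", "spot_index",
                      "x_iso_mm", "y_iso_mm", "mu", "t_start_us", "t_end_us"]


@dataclass(frozen=True)
class LoggedSpot:
    """One delivered spot as reconstructed from the record log.

    Positions are isocenter-plane BEV mm, MU after charge conversion,
    timestamps integer microseconds.
    """

    field_id: str
    layer_index: int
    spot_index: int
    x_log: float
    y_log: float
    mu_log: float
    t_start: int
    t_end: int

    def __post_init__(self) -> None:
        if self.t_end < self.t_start:
            raise InvalidDataError("spot t_end before t_start")
        if self.mu_log < 0:
            raise InvalidDataError("logged MU must be >= 0")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.field_id, self.layer_index, self.spot_index)


@dataclass(frozen=True)
class Event:
    """One events-log entry (timestamp in microseconds)."""

    timestamp: int
    kind: str
    payload: str = ""
    field_id: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise InvalidDataError(f"unknown event kind {self.kind!r}")


@dataclass
class FractionLog:
    """One delivered fraction: spot records plus the event stream."""

    fraction_index: int
    spots: list[LoggedSpot]
    events: list[Event] = dc_field(default_factory=list)
    aborted: bool = False
    ambient: AmbientConditions = dc_field(default_factory=AmbientConditions)
    #: simulator ground truth (offsets, timing bookkeeping); not serialized
    truth: dict = dc_field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.fraction_index < 1:
            raise InvalidDataError("fraction_index must be >= 1")
        keys = [s.key for s in self.spots]
        if len(set(keys)) != len(keys):
            raise IntegrityError("duplicate spot key within fraction")

    def spots_of_field(self, field_id: str) -> list[LoggedSpot]:
        return sorted(
            (s for s in self.spots if s.field_id == field_id),
            key=lambda s: s.t_start,
        )

    def events_of_field(self, field_id: str) -> list[Event]:
        return sorted(
            (e for e in self.events if e.field_id == field_id),
            key=lambda e: e.timestamp,
        )

    @property
    def field_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.spots:
            seen.setdefault(s.field_id)
        return list(seen)

    def spot_map(self) -> dict[tuple[str, int, int], LoggedSpot]:
        return {s.key: s for s in self.spots}


# ---------------------------------------------------------------------------
# Elementary reconstruction operations


def strip_positions(geometry: MachineGeometry) -> np.ndarray:
    """Strip center coordinates (mm) of the position IC, centered on the axis."""
    n = geometry.n_strips
    return (np.arange(n) - (n - 1) / 2.0) * geometry.strip_pitch


def fit_strip_centroid(
    strip_charges: Sequence[float], strip_positions: Sequence[float]
) -> float:
    """Beam centroid (mm) from a Gaussian least-squares fit to strip charges.

    Initialized from the charge-weighted mean and standard deviation;
    resolves the centroid well below the strip pitch.  The charge maximum
    must lie strictly inside the strip range, otherwise the profile is not
    covered and a :class:`CoverageError` is raised.
    """
    q = np.asarray(strip_charges, dtype=float)
    x = np.asarray(strip_positions, dtype=float)
    if q.shape != x.shape or q.ndim != 1:
        raise InvalidDataError("charges and positions must be equal-length 1D")
    if len(q) < 5:
        raise InvalidDataError("need at least 5 strips")
    total = float(q.sum())
    if total <= 0:
        raise InvalidDataError("non-positive total charge")
    imax = int(np.argmax(q))
    if imax in (0, len(q) - 1):
        raise CoverageError("charge peak on boundary strip; beam outside coverage")

    qpos = np.clip(q, 0.0, None)
    mean0 = float((qpos * x).sum() / qpos.sum())
    var0 = float((qpos * (x - mean0) ** 2).sum() / qpos.sum())
    pitch = float(np.median(np.diff(np.sort(x))))
    sd0 = max(math.sqrt(max(var0, 0.0)), 0.5 * pitch)

    def gauss(xv, amp, center, width):
        return amp * np.exp(-0.5 * ((xv - center) / width) ** 2)

    p0 = (float(q[imax]), mean0, sd0)
    with warnings.catch_warnings():
        # noiseless profiles fit perfectly -> singular covariance, irrelevant
        warnings.simplefilter("ignore", OptimizeWarning)
        popt, _ = curve_fit(gauss, x, q, p0=p0, maxfev=10000)
    return float(popt[1])


def project_to_isocenter(
    value_ic: float, axis: str, geometry: MachineGeometry
) -> float:
    """Project an IC-plane coordinate into the isocenter plane.

    Similar triangles from the per-axis virtual source through the IC plane
    (``z_ic`` upstream of the isocenter): ``x_iso = x_ic * sad / (sad - z_ic)``.
    """
    sad = {"x": geometry.sad_x, "y": geometry.sad_y}.get(axis)
    if sad is None:
        raise InvalidDataError(f"axis must be 'x' or 'y', got {axis!r}")
    if sad <= geometry.z_ic:
        raise GeometryError("virtual source must lie upstream of the IC plane")
    return value_ic * sad / (sad - geometry.z_ic)


def charge_to_mu(
    charge: float,
    calibration_factor: float,
    conditions: AmbientConditions,
    geometry: MachineGeometry,
) -> float:
    """Convert accumulated IC charge to MU with air-density correction.

    ``MU = Q * k * (P_ref / P) * (T / T_ref)`` — an open vented chamber
    collects less charge per MU when the air is thinner.
    """
    if calibration_factor <= 0:
        raise InvalidDataError("calibration factor must be positive")
    return (
        charge
        * calibration_factor
        * (geometry.ref_pressure / conditions.pressure)
        * (conditions.temperature / geometry.ref_temperature)
    )


def mu_to_charge(
    mu: float,
    calibration_factor: float,
    conditions: AmbientConditions,
    geometry: MachineGeometry,
) -> float:
    """Inverse of :func:`charge_to_mu` (used by the record writer)."""
    if calibration_factor <= 0:
        raise InvalidDataError("calibration factor must be positive")
    return (
        mu
        / calibration_factor
        / (geometry.ref_pressure / conditions.pressure)
        / (conditions.temperature / geometry.ref_temperature)
    )


# ---------------------------------------------------------------------------
# File dialects


def record_filename(fraction_index: int, field_id: str) -> str:
    return f"fraction{fraction_index:03d}_{field_id}.record.csv"


def events_filename(fraction_index: int, field_id: str) -> str:
    return f"fraction{fraction_index:03d}_{field_id}.events.jsonl"


def write_fraction_logs(
    log: FractionLog,
    plan: TreatmentPlan,
    geometry: MachineGeometry,
    directory: str | Path,
) -> list[Path]:
    """Write one record CSV and one events JSON-lines file per field.

    Isocenter positions are de-projected back to the IC plane and MU back
    to raw charge, so the files look like what the machine writes; the
    reader inverts both steps exactly (floats serialized with ``repr`` are
    round-trip lossless).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    angle_of = {f.field_id: f.gantry_angle for f in plan.fields}
    energy_of = {
        (f.field_id, li): layer.energy
        for f in plan.fields
        for li, layer in enumerate(f.layers)
    }
    fx = geometry.projection_factor("x")
    fy = geometry.projection_factor("y")
    written: list[Path] = []
    for fid in log.field_ids:
        rec_path = directory / record_filename(log.fraction_index, fid)
        with open(rec_path, "w", newline="") as fh:
            fh.write(f"# field_id={fid}\n")
            fh.write(f"# gantry_angle={angle_of[fid]!r}\n")
            fh.write(f"# pressure_hpa={log.ambient.pressure!r}\n")
            fh.write(f"# temperature_k={log.ambient.temperature!r}\n")
            fh.write(f"# calibration_factor={geometry.calibration_factor!r}\n")
            fh.write(",".join(RECORD_COLUMNS_IC) + "\n")
            for s in log.spots_of_field(fid):
                charge = mu_to_charge(
                    s.mu_log, geometry.calibration_factor, log.ambient, geometry
                )
                fh.write(
                    f"{s.layer_index},{energy_of[(fid, s.layer_index)]!r},"
                    f"{s.spot_index},{s.x_log / fx!r},{s.y_log / fy!r},"
                    f"{charge!r},{s.t_start},{s.t_end}\n"
                )
        ev_path = directory / events_filename(log.fraction_index, fid)
        with open(ev_path, "w") as fh:
            for e in log.events_of_field(fid):
                fh.write(
                    json.dumps(
                        {"t_us": e.timestamp, "kind": e.kind,
                         "payload": e.payload, "field_id": e.field_id}
                    )
                    + "\n"
                )
        written += [rec_path, ev_path]
    return written


def _parse_record_file(
    path: Path, geometry: MachineGeometry
) -> tuple[str, AmbientConditions, list[LoggedSpot]]:
    meta: dict[str, str] = {}
    spots: list[LoggedSpot] = []
    header_cols: list[str] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            parts = line.split(",")
            if header_cols is None:
                if parts == RECORD_COLUMNS_IC or parts == RECORD_COLUMNS_ISO:
                    header_cols = parts
                    continue
                raise FormatError(
                    f"{path.name}:{lineno}: unknown record columns {parts!r}"
                )
            if len(parts) != len(header_cols):
                raise FormatError(
                    f"{path.name}:{lineno}: expected {len(header_cols)} fields, "
                    f"got {len(parts)}"
                )
            try:
                row = dict(zip(header_cols, parts))
                li = int(row["layer_index"])
                si = int(row["spot_index"])
                t0 = int(row["t_start_us"])
                t1 = int(row["t_end_us"])
                if header_cols is RECORD_COLUMNS_IC or "x_ic_mm" in row:
                    x = float(row["x_ic_mm"])
                    y = float(row["y_ic_mm"])
                    q = float(row["charge"])
                else:
                    x = float(row["x_iso_mm"])
                    y = float(row["y_iso_mm"])
                    q = float(row["mu"])
            except (KeyError, ValueError) as exc:
                raise FormatError(f"{path.name}:{lineno}: malformed row ({exc})")
            spots.append((li, si, x, y, q, t0, t1))  # type: ignore[arg-type]
    if header_cols is None:
        raise FormatError(f"{path.name}: no column header found")
    if "field_id" not in meta:
        raise FormatError(f"{path.name}: missing '# field_id=' header")
    try:
        ambient = AmbientConditions(
            pressure=float(meta.get("pressure_hpa", geometry.ref_pressure)),
            temperature=float(meta.get("temperature_k", geometry.ref_temperature)),
        )
        cal = float(meta.get("calibration_factor", geometry.calibration_factor))
    except ValueError as exc:
        raise FormatError(f"{path.name}: malformed header value ({exc})")

    field_id = meta["field_id"]
    pre_projected = "x_iso_mm" in header_cols
    fx = geometry.projection_factor("x")
    fy = geometry.projection_factor("y")
    out: list[LoggedSpot] = []
    for li, si, x, y, q, t0, t1 in spots:
        if pre_projected:
            x_iso, y_iso, mu = x, y, q
        else:
            x_iso = x * fx
            y_iso = y * fy
            mu = charge_to_mu(q, cal, ambient, geometry)
        out.append(
            LoggedSpot(field_id, li, si, x_iso, y_iso, mu, t0, t1)
        )
    return field_id, ambient, out


def _parse_events_file(path: Path, field_id: str) -> list[Event]:
    events: list[Event] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                ev = Event(
                    timestamp=int(obj["t_us"]),
                    kind=str(obj["kind"]),
                    payload=str(obj.get("payload", "")),
                    field_id=str(obj.get("field_id", field_id)),
                )
            except (KeyError, ValueError, InvalidDataError, json.JSONDecodeError) as exc:
                raise FormatError(f"{path.name}:{lineno}: malformed event ({exc})")
            events.append(ev)
    _validate_events(events, path.name)
    return events


def _validate_events(events: list[Event], name: str) -> None:
    last_t = None
    depth = 0
    for e in events:
        if last_t is not None and e.timestamp < last_t:
            raise InvalidDataError(f"{name}: non-monotone event timestamps")
        last_t = e.timestamp
        if e.kind == "INTERLOCK_START":
            depth += 1
            if depth > 1:
                raise IntegrityError(f"{name}: nested INTERLOCK_START")
        elif e.kind == "INTERLOCK_END":
            depth -= 1
            if depth < 0:
                raise IntegrityError(f"{name}: INTERLOCK_END without start")
    if depth != 0:
        raise IntegrityError(f"{name}: unpaired interlock events")


def read_fraction(
    record_paths: Sequence[str | Path],
    events_paths: Sequence[str | Path],
    plan: TreatmentPlan,
    geometry: MachineGeometry,
    *,
    fraction_index: int = 1,
) -> FractionLog:
    """Assemble a :class:`FractionLog` from record/events files.

    Spots are matched to the plan by ``(field_id, layer_index, spot_index)``
    (deliveries preserve plan ordering, so matching by key is exact).  The
    fraction is flagged aborted when fewer spots were logged than planned.
    """
    plan_keys = {
        (fid, li, si) for fid, _, li, _, si, _ in plan.iter_spots()
    }
    all_spots: list[LoggedSpot] = []
    ambient = AmbientConditions()
    seen_fields: list[str] = []
    for rp in record_paths:
        field_id, ambient, spots = _parse_record_file(Path(rp), geometry)
        if field_id not in {f.field_id for f in plan.fields}:
            raise IntegrityError(f"record field {field_id!r} not in plan")
        seen_fields.append(field_id)
        all_spots.extend(spots)

    keys = [s.key for s in all_spots]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise IntegrityError(f"duplicate spot key(s) in records: {dupes[:3]}")
    unknown = set(keys) - plan_keys
    if unknown:
        raise IntegrityError(f"logged spot(s) not in plan: {sorted(unknown)[:3]}")

    events: list[Event] = []
    for ep, fid in zip(events_paths, seen_fields):
        events.extend(_parse_events_file(Path(ep), fid))

    aborted = len(all_spots) < len(plan_keys)
    return FractionLog(
        fraction_index=fraction_index,
        spots=all_spots,
        events=events,
        aborted=aborted,
        ambient=ambient,
    )
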