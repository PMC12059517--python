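"""Global 3D gamma-index comparison of dose distributions.

For every reference voxel r above the low-dose cutoff, the gamma index
is the minimum over evaluation sample points e of

    gamma(r) = min_e sqrt( |r - e|^2 / dta^2
                         + (D_eval(e) - D_ref(r))^2 / delta^2 ),

with delta = dose_percent/100 * normalization (global criterion; the
normalization is the reference dose maximum, held fixed across all
fraction comparisons).  Evaluation dose is sampled by trilinear
interpolation on a rectangular search lattice with step
``interp_fraction * dta`` out to ``search_radius_factor * dta``.  A
voxel passes when gamma <= 1; the pass rate is the passing percentage
of evaluated (above-cutoff) reference voxels.

The search processes lattice offsets in shells of increasing distance
and prunes a voxel as soon as the next shell's distance term alone can
no longer improve its current best gamma — mathematically identical to
the exhaustive dense search over the same lattice, just faster.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates, maximum_filter, minimum_filter

from .errors import GeometryError, InvalidDataError
from .dose import DoseGrid


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma settings: global dose difference (%), DTA (mm), cutoffs."""

    dose_percent: float = 1.0
    dta: float = 1.0
    cutoff_fraction: float = 0.10
    interp_fraction: float = 0.10
    search_radius_factor: float = 3.0
    normalization: float | None = None  # None: reference maximum

    def __post_init__(self) -> None:
        if min(self.dose_percent, self.dta, self.cutoff_fraction,
               self.interp_fraction, self.search_radius_factor) <= 0:
            raise InvalidDataError("all gamma criteria must be positive")
        if self.interp_fraction > 1:
            raise InvalidDataError("interp_fraction must be <= 1")
        if self.normalization is not None and self.normalization <= 0:
            raise InvalidDataError("normalization must be positive")

    def label(self) -> str:
        return f"{self.dose_percent:g}%/{self.dta:g}mm"


@dataclass
class GammaResult:
    """Outcome of one 3D gamma comparison."""

    pass_rate: float            # % of evaluated voxels with gamma <= 1
    n_evaluated: int
    n_passed: int
    gamma_map: np.ndarray | None = None   # full grid, NaN below cutoff

    def __post_init__(self) -> None:
        if not 0.0 <= self.pass_rate <= 100.0:
            raise InvalidDataError("pass rate must lie in [0, 100]")


@lru_cache(maxsize=8)
def _lattice_shells(n_steps: int) -> tuple[tuple[np.ndarray, np.ndarray], ...]:
    """Integer lattice offsets within radius ``n_steps``, binned into
    unit-thickness shells sorted by distance; each shell is
    ``(offsets (k,3) int, distances (k,) float in steps)``."""
    r = np.arange(-n_steps, n_steps + 1)
    gx, gy, gz = np.meshgrid(r, r, r, indexing="ij")
    offs = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    dist = np.linalg.norm(offs, axis=1)
    keep = dist <= n_steps
    offs, dist = offs[keep], dist[keep]
    order = np.argsort(dist, kind="stable")
    offs, dist = offs[order], dist[order]
    shell_idx = np.floor(dist).astype(int)
    shells = []
    for k in range(shell_idx.max() + 1):
        m = shell_idx == k
        if m.any():
            shells.append((offs[m], dist[m]))
    return tuple(shells)


def _sample_eval(evaluation: DoseGrid, points: np.ndarray) -> np.ndarray:
    """Trilinear sample of the evaluation dose at world points (N, 3).

    Points outside the evaluation extent clamp to the nearest voxel
    (boundary voxels are evaluated against the available extent).
    """
    coords = (points - evaluation.origin) / evaluation.spacing
    return map_coordinates(evaluation.values, coords.T, order=1,
                           mode="nearest")


def gamma_index(
    reference: DoseGrid,
    evaluation: DoseGrid,
    criteria: GammaCriteria | None = None,
    *,
    retain_map: bool = False,
    early_exit: bool = True,
    max_chunk: int = 4_000_000,
) -> GammaResult:
    """3D global gamma of ``evaluation`` against ``reference``.

    ``early_exit=False`` disables shell pruning (same lattice, exhaustive
    minimum) and exists to verify that pruning never changes a result.
    """
    criteria = criteria or GammaCriteria()
    if not np.allclose(reference.spacing, evaluation.spacing) or \
            not np.allclose(reference.origin, evaluation.origin) or \
            reference.shape != evaluation.shape:
        # grids may differ in principle; this implementation requires a
        # shared frame, which the pipeline always produces
        raise GeometryError("reference and evaluation grids must share a frame")

    norm = criteria.normalization
    if norm is None:
        norm = float(reference.values.max())
    if norm <= 0:
        raise InvalidDataError("normalization must be positive")
    delta = criteria.dose_percent / 100.0 * norm
    cutoff = criteria.cutoff_fraction * norm

    ref_vals = reference.values
    eval_mask = ref_vals >= cutoff
    n_eval = int(eval_mask.sum())
    if n_eval == 0:
        raise InvalidDataError("no reference voxel above the low-dose cutoff")

    ridx = np.argwhere(eval_mask)
    rpts = reference.origin + ridx * reference.spacing
    dref = ref_vals[eval_mask]

    step = criteria.interp_fraction * criteria.dta
    n_steps = int(round(criteria.search_radius_factor / criteria.interp_fraction))
    shells = _lattice_shells(n_steps)

    best = np.full(n_eval, np.inf)
    active = np.ones(n_eval, dtype=bool)
    # Local dose-range bounds per search radius let shells be skipped when
    # even the most favourable dose value inside the shell cannot improve a
    # voxel's current best gamma.  Trilinear interpolation at any point
    # within world radius r of a voxel center only mixes grid values whose
    # index offset per axis is at most floor(r / spacing) + 1, so min/max
    # filters of that footprint bound the attainable evaluation dose.
    filter_cache: dict[tuple[int, ...], tuple[np.ndarray, np.ndarray]] = {}

    def _dose_bound(d_hi_mm: float) -> np.ndarray:
        sizes = tuple(
            2 * (int(d_hi_mm // evaluation.spacing[k]) + 1) + 1
            for k in range(3)
        )
        if sizes not in filter_cache:
            filter_cache[sizes] = (
                minimum_filter(evaluation.values, size=sizes, mode="nearest")[
                    eval_mask],
                maximum_filter(evaluation.values, size=sizes, mode="nearest")[
                    eval_mask],
            )
        lo, hi = filter_cache[sizes]
        below = np.clip(lo - dref, 0.0, None)
        above = np.clip(dref - hi, 0.0, None)
        return np.maximum(below, above) / delta

    for offs, dists in shells:
        d_lo = float(dists.min()) * step
        d_hi = float(dists.max()) * step
        dist_term2 = (dists * step / criteria.dta) ** 2
        if early_exit:
            active &= best > d_lo / criteria.dta
            if not active.any():
                break
            bound = np.hypot(d_lo / criteria.dta, _dose_bound(d_hi))
            aidx = np.flatnonzero(active & (bound < best))
            if aidx.size == 0:
                continue
        else:
            aidx = np.arange(n_eval)
        # chunk voxels so points arrays stay bounded
        vox_per_chunk = max(1, max_chunk // len(offs))
        for c0 in range(0, len(aidx), vox_per_chunk):
            sel = aidx[c0:c0 + vox_per_chunk]
            pts = rpts[sel][:, None, :] + (offs * step)[None, :, :]
            de = _sample_eval(evaluation, pts.reshape(-1, 3)).reshape(
                len(sel), len(offs))
            g2 = dist_term2[None, :] + ((de - dref[sel, None]) / delta) ** 2
            best[sel] = np.minimum(best[sel], np.sqrt(g2.min(axis=1)))

    n_passed = int((best <= 1.0).sum())
    gmap = None
    if retain_map:
        gmap = np.full(reference.shape, np.nan)
        gmap[eval_mask] = best
    return GammaResult(
        pass_rate=100.0 * n_passed / n_eval,
        n_evaluated=n_eval,
        n_passed=n_passed,
        gamma_map=gmap,
    )


def gamma_series(
    reference: DoseGrid,
    fraction_doses: Sequence[DoseGrid],
    criteria: GammaCriteria | None = None,
) -> list[float]:
    """Gamma pass rate per fraction dose against one fixed reference.

    The normalization is taken from the reference maximum once and reused
    for every fraction, so pass rates are comparable across the series.
    """
    if len(fraction_doses) == 0:
        raise InvalidDataError("empty fraction dose list")
    criteria = criteria or GammaCriteria()
    if criteria.normalization is None:
        criteria = GammaCriteria(
            dose_percent=criteria.dose_percent, dta=criteria.dta,
            cutoff_fraction=criteria.cutoff_fraction,
            interp_fraction=criteria.interp_fraction,
            search_radius_factor=criteria.search_radius_factor,
            normalization=float(reference.values.max()),
        )
    return [
        gamma_index(reference, ev, criteria).pass_rate for ev in fraction_doses
    ]
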