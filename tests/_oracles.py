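"""Independent brute-force oracles used to verify the analysis code.

Everything here is deliberately written as plain loops / textbook
formulas, independent of the package's vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.interpolate import RegularGridInterpolator


def brute_mean_deviation(logged, planned) -> float:
    total = 0.0
    for v in logged:
        total += v - planned
    return total / len(logged)


def brute_corrected_sd(values) -> float:
    n = len(values)
    mean = sum(values) / n
    ssq = 0.0
    for v in values:
        ssq += (v - mean) ** 2
    return math.sqrt(ssq / (n - 1))


def brute_mean_distance(xs, ys, x_plan, y_plan) -> float:
    total = 0.0
    for x, y in zip(xs, ys):
        total += math.sqrt((x - x_plan) ** 2 + (y - y_plan) ** 2)
    return total / len(xs)


def brute_lambda(mus, ds, tol) -> float:
    num = 0.0
    den = 0.0
    for m, d in zip(mus, ds):
        den += m
        if d < tol:
            num += m
    return 100.0 * num / den


def brute_pearson(a, b) -> float:
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    cov = sa = sb = 0.0
    for x, y in zip(a, b):
        cov += (x - ma) * (y - mb)
        sa += (x - ma) ** 2
        sb += (y - mb) ** 2
    return cov / math.sqrt(sa * sb)


def brute_box_summary(values):
    """Median/quartiles (linear interpolation) and 1.5*IQR whiskers."""
    v = sorted(float(x) for x in values)
    n = len(v)

    def quantile(q):
        pos = q * (n - 1)
        lo = int(math.floor(pos))
        hi = int(math.ceil(pos))
        frac = pos - lo
        return v[lo] * (1 - frac) + v[hi] * frac

    q1, med, q3 = quantile(0.25), quantile(0.5), quantile(0.75)
    iqr = q3 - q1
    inside = [x for x in v if q1 - 1.5 * iqr <= x <= q3 + 1.5 * iqr]
    return med, q1, q3, inside[0], inside[-1]


def dense_gamma(reference, evaluation, criteria):
    """Exhaustive dense-lattice 3D gamma, no early exit.

    Independent implementation: RegularGridInterpolator with sample
    points clipped to the evaluation extent (equivalent to
    nearest-edge clamping), full minimum over the whole lattice.
    Returns (pass_rate_percent, gamma_values, voxel_indices).
    """
    norm = criteria.normalization
    if norm is None:
        norm = float(reference.values.max())
    delta = criteria.dose_percent / 100.0 * norm
    cutoff = criteria.cutoff_fraction * norm

    step = criteria.interp_fraction * criteria.dta
    n_steps = int(round(criteria.search_radius_factor / criteria.interp_fraction))
    r = np.arange(-n_steps, n_steps + 1)
    gx, gy, gz = np.meshgrid(r, r, r, indexing="ij")
    offs = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]).astype(float)
    dist = np.linalg.norm(offs, axis=1)
    keep = dist <= n_steps
    offs = offs[keep] * step
    dist_mm = dist[keep] * step

    axes = [
        evaluation.origin[k]
        + evaluation.spacing[k] * np.arange(evaluation.shape[k])
        for k in range(3)
    ]
    interp = RegularGridInterpolator(axes, evaluation.values)
    lo = np.array([a[0] for a in axes])
    hi = np.array([a[-1] for a in axes])

    vox = np.argwhere(reference.values >= cutoff)
    gammas = np.empty(len(vox))
    for i, idx in enumerate(vox):
        center = reference.origin + idx * reference.spacing
        dref = reference.values[tuple(idx)]
        pts = np.clip(center[None, :] + offs, lo, hi)
        de = interp(pts)
        g2 = (dist_mm / criteria.dta) ** 2 + ((de - dref) / delta) ** 2
        gammas[i] = math.sqrt(float(g2.min()))
    pass_rate = 100.0 * float((gammas <= 1.0).sum()) / len(gammas)
    return pass_rate, gammas, vox


def random_blob_dose(rng, n=12, spacing=3.0, n_blobs=3):
    """Smooth random dose: a few 3D Gaussian blobs, max-normalized."""
    from pbs_lfqa import DoseGrid

    ax = spacing * np.arange(n)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    vals = np.zeros((n, n, n))
    for _ in range(n_blobs):
        c = rng.uniform(0.3, 0.7, size=3) * ax[-1]
        w = rng.uniform(0.8, 1.5) * spacing
        amp = rng.uniform(0.5, 1.0)
        vals += amp * np.exp(
            -((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2) / (2 * w**2)
        )
    return DoseGrid(np.zeros(3), np.full(3, spacing), vals / vals.max())
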