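"""Spot-based log-file pass rate Lambda(D) and its coupling to gamma.

Lambda is the MU-weighted fraction of spots delivered within a tolerance
distance D of their reference position,

    Lambda_i(D) = sum_s MU_{i,s} * [d_{i,s} < D] / sum_s MU_{i,s},

evaluated per fraction i over all recorded spots s, with strict
inequality in the Iverson bracket and MU taken from the fraction's own
log record.  d_{i,s} is the 2D Euclidean distance of the logged (x, y)
to the reference position — either the planned position or the first
delivered fraction's logged position (a surrogate for a pre-treatment
QA delivery).  Per plan, the fraction-wise Lambda(1 mm) series is
correlated with the Gamma(1%/1 mm) series via the Pearson coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import (
    InsufficientDataError,
    InvalidDataError,
    UndefinedCorrelationError,
)
from .dose import BeamModel, DoseGrid, build_logfile_plan, reconstruct_dose
from .gamma import GammaCriteria, gamma_series
from .logfile_io import FractionLog
from .plans import TreatmentPlan


def lambda_pass_rate(
    mu: Sequence[float], d: Sequence[float], tolerance_d: float = 1.0
) -> float:
    """MU-weighted percentage of spots with distance strictly below D."""
    mu_arr = np.asarray(mu, dtype=float)
    d_arr = np.asarray(d, dtype=float)
    if mu_arr.shape != d_arr.shape or mu_arr.ndim != 1:
        raise InvalidDataError("mu and d must be equal-length 1D sequences")
    if np.any(d_arr < 0):
        raise InvalidDataError("distances must be >= 0")
    total = float(mu_arr.sum())
    if total <= 0:
        raise InvalidDataError("total MU must be positive")
    # divide before scaling so a full pass is exactly 100.0
    return 100.0 * (float(mu_arr[d_arr < tolerance_d].sum()) / total)


def spot_distance(
    x_log: float | np.ndarray,
    y_log: float | np.ndarray,
    x_ref: float | np.ndarray,
    y_ref: float | np.ndarray,
) -> float | np.ndarray:
    """2D Euclidean distance of logged to reference spot position (mm)."""
    return np.hypot(np.asarray(x_log) - np.asarray(x_ref),
                    np.asarray(y_log) - np.asarray(y_ref))


def pearson(series_a: Sequence[float], series_b: Sequence[float]) -> float:
    """Sample Pearson product-moment correlation of two series.

    Raises :class:`UndefinedCorrelationError` when either series has zero
    variance — callers report the correlation as missing, never as 0.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidDataError("series must be equal-length 1D sequences")
    if a.size < 3:
        raise InvalidDataError("need at least 3 points for a correlation")
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        raise UndefinedCorrelationError("zero variance in at least one series")
    return float(sps.pearsonr(a, b).statistic)


@dataclass
class PassRateSeries:
    """Per-fraction Lambda and Gamma against one reference choice."""

    plan_id: str
    reference_kind: str                      # "original_plan" | "first_fraction"
    fraction_indices: list[int]
    lambda_percent: list[float]
    gamma_percent: list[float]
    pearson_r: float | None
    tolerance_d: float = 1.0
    gamma_label: str = "1%/1mm"
    n_excluded_aborted: int = 0

    def summary(self) -> dict:
        return {
            "plan_id": self.plan_id,
            "reference_kind": self.reference_kind,
            "lambda_mean": float(np.mean(self.lambda_percent)),
            "lambda_min": float(np.min(self.lambda_percent)),
            "gamma_mean": float(np.mean(self.gamma_percent)),
            "gamma_min": float(np.min(self.gamma_percent)),
            "pearson_r": self.pearson_r,
            "n_fractions": len(self.fraction_indices),
            "n_excluded_aborted": self.n_excluded_aborted,
        }


def _reference_positions(
    plan: TreatmentPlan,
    reference_kind: str,
    first_fraction: FractionLog | None,
) -> dict[tuple[str, int, int], tuple[float, float]]:
    if reference_kind == "original_plan":
        return {
            (fid, li, si): (s.x, s.y)
            for fid, _a, li, _e, si, s in plan.iter_spots()
        }
    if reference_kind == "first_fraction":
        assert first_fraction is not None
        return {
            s.key: (s.x_log, s.y_log) for s in first_fraction.spots
        }
    raise InvalidDataError(f"unknown reference_kind {reference_kind!r}")


def fraction_distances(
    fraction: FractionLog,
    reference: dict[tuple[str, int, int], tuple[float, float]],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-spot (MU, distance-to-reference) arrays for one fraction."""
    mus = []
    ds = []
    for s in fraction.spots:
        ref = reference.get(s.key)
        if ref is None:
            raise InvalidDataError(f"no reference position for spot {s.key}")
        mus.append(s.mu_log)
        ds.append(float(spot_distance(s.x_log, s.y_log, ref[0], ref[1])))
    return np.asarray(mus), np.asarray(ds)


def build_series(
    plan: TreatmentPlan,
    fractions: Sequence[FractionLog],
    *,
    reference_kind: str = "original_plan",
    tolerance_d: float = 1.0,
    criteria: GammaCriteria | None = None,
    grid: DoseGrid | None = None,
    beam: BeamModel | None = None,
    entry_depth: float = 40.0,
    fraction_doses: Sequence[DoseGrid] | None = None,
    reference_dose: DoseGrid | None = None,
) -> PassRateSeries:
    """Fraction-wise Lambda and Gamma series against one reference choice.

    Aborted fractions are excluded.  With ``reference_kind="original_plan"``
    the reference is the plan and its reconstructed dose; with
    ``"first_fraction"`` it is the first usable fraction's logged positions
    and reconstructed dose (that fraction stays in the series and scores
    100% on both metrics by construction, and the gamma normalization
    follows the fraction-1 dose maximum).

    Pre-computed ``fraction_doses`` (one per usable fraction, in order) and
    ``reference_dose`` may be passed to avoid re-running the dose engine.
    """
    criteria = criteria or GammaCriteria()
    usable = [f for f in fractions if not f.aborted]
    n_excluded = len(fractions) - len(usable)
    if len(usable) < 3:
        raise InsufficientDataError(
            f"need >= 3 non-aborted fractions, have {len(usable)}"
        )

    first = usable[0] if reference_kind == "first_fraction" else None
    refpos = _reference_positions(plan, reference_kind, first)

    if fraction_doses is None:
        fraction_doses = [
            reconstruct_dose(build_logfile_plan(plan, f), grid, beam,
                             entry_depth)
            for f in usable
        ]
    if reference_dose is None:
        if reference_kind == "original_plan":
            reference_dose = reconstruct_dose(plan, grid, beam, entry_depth)
        else:
            reference_dose = fraction_doses[0]

    gammas = gamma_series(reference_dose, fraction_doses, criteria)
    lambdas = []
    for f in usable:
        mu, d = fraction_distances(f, refpos)
        lambdas.append(lambda_pass_rate(mu, d, tolerance_d))

    try:
        r: float | None = pearson(lambdas, gammas)
    except UndefinedCorrelationError:
        r = None

    return PassRateSeries(
        plan_id=plan.plan_id,
        reference_kind=reference_kind,
        fraction_indices=[f.fraction_index for f in usable],
        lambda_percent=lambdas,
        gamma_percent=gammas,
        pearson_r=r,
        tolerance_d=tolerance_d,
        gamma_label=criteria.label(),
        n_excluded_aborted=n_excluded,
    )
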