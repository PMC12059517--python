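"""Per-spot accuracy and reproducibility statistics over repeated fractions.

For every planned spot the accuracy of a parameter (x, y position or MU)
is the sample mean deviation of the logged values from the planned value
over the N delivered fractions,

    mu_s = (1/N) * sum_i (L_{i,s} - P_s),

and the reproducibility is the corrected (N-1 denominator) sample
standard deviation of the N logged values,

    sigma_s = sqrt( (1/(N-1)) * sum_i (L_{i,s} - Lbar_s)^2 ).

The 2D distance accuracy is the mean over fractions of the per-fraction
Euclidean distance d_{i,s} = hypot(dx, dy) — by Jensen's inequality it is
always >= hypot(mu_x, mu_y).  Aggregation mirrors clinical reporting:
per-plan and per-gantry-angle mean, worst (largest magnitude, sign
preserved) and box-plot style distribution summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidDataError
from .logfile_io import FractionLog
from .plans import TreatmentPlan

#: Fraction count below which reproducibility estimates get a warning.
RECOMMENDED_MIN_FRACTIONS = 15

QUANTITIES = ("mu_x", "mu_y", "sigma_x", "sigma_y", "mu_mu", "sigma_mu",
              "mean_distance")


def spot_accuracy(values_logged: Sequence[float], value_planned: float) -> float:
    """Mean deviation of logged values from the planned value."""
    v = np.asarray(values_logged, dtype=float)
    if v.size == 0:
        raise InvalidDataError("no logged values")
    if v.size < RECOMMENDED_MIN_FRACTIONS:
        warnings.warn(
            f"accuracy estimated from {v.size} < {RECOMMENDED_MIN_FRACTIONS} "
            "fractions", stacklevel=2,
        )
    return float(np.mean(v - value_planned))


def spot_reproducibility(values_logged: Sequence[float]) -> float:
    """Corrected (N-1) sample standard deviation of the logged values."""
    v = np.asarray(values_logged, dtype=float)
    if v.size < 2:
        raise InvalidDataError("reproducibility needs at least 2 fractions")
    return float(np.std(v, ddof=1))


def spot_distance_accuracy(
    x_logged: Sequence[float],
    y_logged: Sequence[float],
    x_plan: float,
    y_plan: float,
) -> float:
    """Mean over fractions of the per-fraction 2D distance to the plan."""
    x = np.asarray(x_logged, dtype=float)
    y = np.asarray(y_logged, dtype=float)
    if x.shape != y.shape or x.size == 0:
        raise InvalidDataError("x and y lists must be equal-length and non-empty")
    return float(np.mean(np.hypot(x - x_plan, y - y_plan)))


def compute_spot_statistics(
    plan: TreatmentPlan, fractions: Sequence[FractionLog]
) -> pd.DataFrame:
    """Per-spot statistics table over all non-aborted fractions.

    Aborted fractions are dropped entirely (their partial spot lists would
    bias per-spot sample sizes).  Requires >= 2 usable fractions.  Returns
    one row per planned spot with columns ``field_id, layer_index,
    spot_index, gantry_angle, x_plan, y_plan, mu_plan, n_fractions, mu_x,
    mu_y, mu_mu, sigma_x, sigma_y, sigma_mu, mean_distance``.
    """
    usable = [f for f in fractions if not f.aborted]
    n = len(usable)
    if n < 2:
        raise InvalidDataError("need at least 2 non-aborted fractions")
    if n < RECOMMENDED_MIN_FRACTIONS:
        warnings.warn(
            f"spot statistics over {n} < {RECOMMENDED_MIN_FRACTIONS} fractions",
            stacklevel=2,
        )

    keys = []
    plan_rows = []
    for fid, ang, li, _e, si, s in plan.iter_spots():
        keys.append((fid, li, si))
        plan_rows.append((fid, li, si, ang, s.x, s.y, s.mu))
    key_index = {k: i for i, k in enumerate(keys)}
    nspots = len(keys)

    X = np.empty((n, nspots))
    Y = np.empty((n, nspots))
    M = np.empty((n, nspots))
    for i, frac in enumerate(usable):
        smap = frac.spot_map()
        if set(smap) != set(keys):
            raise InvalidDataError(
                f"fraction {frac.fraction_index} spot keys do not match plan"
            )
        for k, j in key_index.items():
            s = smap[k]
            X[i, j] = s.x_log
            Y[i, j] = s.y_log
            M[i, j] = s.mu_log

    df = pd.DataFrame(
        plan_rows,
        columns=["field_id", "layer_index", "spot_index", "gantry_angle",
                 "x_plan", "y_plan", "mu_plan"],
    )
    df["n_fractions"] = n
    df["mu_x"] = X.mean(axis=0) - df["x_plan"].to_numpy()
    df["mu_y"] = Y.mean(axis=0) - df["y_plan"].to_numpy()
    df["mu_mu"] = M.mean(axis=0) - df["mu_plan"].to_numpy()
    df["sigma_x"] = X.std(axis=0, ddof=1)
    df["sigma_y"] = Y.std(axis=0, ddof=1)
    df["sigma_mu"] = M.std(axis=0, ddof=1)
    df["mean_distance"] = np.hypot(
        X - df["x_plan"].to_numpy(), Y - df["y_plan"].to_numpy()
    ).mean(axis=0)
    return df


@dataclass(frozen=True)
class DistributionSummary:
    """Box-plot style summary: quartiles plus 1.5*IQR whiskers."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    n: int

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "DistributionSummary":
        v = np.sort(np.asarray(values, dtype=float))
        if v.size == 0:
            raise InvalidDataError("empty value list")
        q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
        iqr = q3 - q1
        inside = v[(v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)]
        return cls(float(med), float(q1), float(q3),
                   float(inside[0]), float(inside[-1]), int(v.size))


def worst_value(values: Sequence[float]) -> float:
    """Value of largest magnitude, sign preserved (clinical 'worst')."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InvalidDataError("empty value list")
    return float(v[np.argmax(np.abs(v))])


def aggregate(
    stats: pd.DataFrame, group_by: str = "plan"
) -> dict[object, dict[str, dict]]:
    """Aggregate per-spot statistics per plan or per gantry angle.

    Returns ``{group: {quantity: {"mean", "worst", "summary"}}}`` where
    quantity runs over mu_x, mu_y, sigma_x, sigma_y, mu_mu, sigma_mu and
    mean_distance.  ``group_by="plan"`` yields the single group ``"plan"``;
    ``group_by="gantry_angle"`` groups each spot by its field's angle.
    """
    if stats.empty:
        raise InvalidDataError("empty statistics table")
    if group_by == "plan":
        groups = {"plan": stats}
    elif group_by == "gantry_angle":
        groups = {float(a): g for a, g in stats.groupby("gantry_angle")}
    else:
        raise InvalidDataError(f"unknown group key {group_by!r}")

    out: dict[object, dict[str, dict]] = {}
    for gkey, g in groups.items():
        out[gkey] = {}
        for q in QUANTITIES:
            vals = g[q].to_numpy()
            out[gkey][q] = {
                "mean": float(vals.mean()),
                "worst": worst_value(vals),
                "summary": DistributionSummary.from_values(vals),
            }
    return out


def aggregate_table(stats: pd.DataFrame, group_by: str = "plan") -> pd.DataFrame:
    """Flat CSV-friendly version of :func:`aggregate`."""
    agg = aggregate(stats, group_by)
    rows = []
    for gkey, quantities in agg.items():
        for q, d in quantities.items():
            s: DistributionSummary = d["summary"]
            rows.append(
                {"group": gkey, "quantity": q, "mean": d["mean"],
                 "worst": d["worst"], "median": s.median, "q1": s.q1,
                 "q3": s.q3, "whisker_low": s.whisker_low,
                 "whisker_high": s.whisker_high, "n": s.n}
            )
    return pd.DataFrame(rows)
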