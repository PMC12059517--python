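"""Delivery-time decomposition and reproducibility from log timestamps.

Each field delivery decomposes exactly into cumulative spot drill time
(beam on, per-spot t_end - t_start), spot-switch time (gaps between
consecutive spots within an energy layer), energy-switch time (gaps
between layers) and interlock time (machine safety interruptions,
identified from INTERLOCK_START/END event pairs and excised from
whichever gap or drill interval they overlap).  The delivery time
excludes interlocks; beam-off time between fields is never counted.
All bookkeeping is integer microseconds, reported in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import IntegrityError, InvalidDataError
from .logfile_io import Event, FractionLog, LoggedSpot

US_PER_S = 1_000_000


@dataclass(frozen=True)
class TimingBreakdown:
    """Timing components of one field delivery (seconds)."""

    field_id: str
    fraction_index: int
    drill_total: float
    spot_switch_total: float
    energy_switch_total: float
    interlock_total: float
    had_interlock: bool

    @property
    def delivery_time(self) -> float:
        """Total field delivery time excluding interlocks, s."""
        return self.drill_total + self.spot_switch_total + self.energy_switch_total


def _interlock_intervals(events: Sequence[Event]) -> list[tuple[int, int]]:
    starts: list[int] = []
    out: list[tuple[int, int]] = []
    last_t = None
    for e in sorted(events, key=lambda e: e.timestamp):
        if last_t is not None and e.timestamp < last_t:
            raise InvalidDataError("non-monotone event timestamps")
        last_t = e.timestamp
        if e.kind == "INTERLOCK_START":
            if starts:
                raise IntegrityError("nested/unpaired INTERLOCK_START")
            starts.append(e.timestamp)
        elif e.kind == "INTERLOCK_END":
            if not starts:
                raise IntegrityError("INTERLOCK_END without matching start")
            out.append((starts.pop(), e.timestamp))
    if starts:
        raise IntegrityError("unpaired INTERLOCK_START at end of stream")
    return out


def _overlap(a0: int, a1: int, intervals: Sequence[tuple[int, int]]) -> int:
    """Total microseconds of [a0, a1] covered by the interlock intervals."""
    return sum(max(0, min(a1, i1) - max(a0, i0)) for i0, i1 in intervals)


def decompose_field_timing(
    spots: Sequence[LoggedSpot], events: Sequence[Event]
) -> TimingBreakdown:
    """Decompose one field's delivery into drill/switch/interlock components.

    ``spots`` must be the time-ordered records of a single field; layer
    boundaries are inferred from ``layer_index`` changes (LAYER_* events
    are informational).  Any portion of a drill interval or gap covered by
    an interlock is attributed to ``interlock_total`` and excluded from
    its original category, so component conservation holds exactly:
    drill + spot_switch + energy_switch + interlock
    = last t_end - first t_start.
    """
    if not spots:
        raise InvalidDataError("no spots in field")
    ordered = sorted(spots, key=lambda s: s.t_start)
    fids = {s.field_id for s in ordered}
    if len(fids) != 1:
        raise InvalidDataError(f"spots from multiple fields: {sorted(fids)}")
    for a, b in zip(ordered, ordered[1:]):
        if b.t_start < a.t_end:
            raise InvalidDataError("overlapping spot intervals")

    window = (ordered[0].t_start, ordered[-1].t_end)
    interlocks = [
        (max(i0, window[0]), min(i1, window[1]))
        for i0, i1 in _interlock_intervals(events)
    ]
    interlocks = [(i0, i1) for i0, i1 in interlocks if i1 > i0]

    drill = 0
    ss = 0
    es = 0
    for s in ordered:
        drill += (s.t_end - s.t_start) - _overlap(s.t_start, s.t_end, interlocks)
    for a, b in zip(ordered, ordered[1:]):
        gap = (b.t_start - a.t_end) - _overlap(a.t_end, b.t_start, interlocks)
        if b.layer_index == a.layer_index:
            ss += gap
        else:
            es += gap
    il = sum(i1 - i0 for i0, i1 in interlocks)

    return TimingBreakdown(
        field_id=ordered[0].field_id,
        fraction_index=0,
        drill_total=drill / US_PER_S,
        spot_switch_total=ss / US_PER_S,
        energy_switch_total=es / US_PER_S,
        interlock_total=il / US_PER_S,
        had_interlock=bool(interlocks),
    )


def decompose_fraction_timing(fraction: FractionLog) -> list[TimingBreakdown]:
    """Per-field timing breakdowns of one fraction."""
    out = []
    for fid in fraction.field_ids:
        bd = decompose_field_timing(
            fraction.spots_of_field(fid), fraction.events_of_field(fid)
        )
        out.append(
            TimingBreakdown(
                field_id=bd.field_id,
                fraction_index=fraction.fraction_index,
                drill_total=bd.drill_total,
                spot_switch_total=bd.spot_switch_total,
                energy_switch_total=bd.energy_switch_total,
                interlock_total=bd.interlock_total,
                had_interlock=bd.had_interlock,
            )
        )
    return out


@dataclass(frozen=True)
class TimingSummary:
    """Delivery-time reproducibility per field and per plan."""

    per_field: dict[str, tuple[float, float]]   # field -> (mean s, 2*sd s)
    plan_mean: float
    plan_two_sigma: float
    interlock_free_percent: float
    n_field_deliveries: int


def timing_summary(breakdowns: Sequence[TimingBreakdown]) -> TimingSummary:
    """Mean and double standard deviation of delivery times.

    Per field: statistics of that field's delivery time across fractions.
    Per plan: statistics of the per-fraction sum over fields (gantry
    rotation / beam-off between fields excluded).  Also reports the
    percentage of field deliveries without any interlock.
    """
    if not breakdowns:
        raise InvalidDataError("no timing breakdowns")
    df = pd.DataFrame(
        {
            "field_id": [b.field_id for b in breakdowns],
            "fraction": [b.fraction_index for b in breakdowns],
            "t": [b.delivery_time for b in breakdowns],
            "clean": [not b.had_interlock for b in breakdowns],
        }
    )

    def mean_2sd(x: pd.Series) -> tuple[float, float]:
        if len(x) < 2:
            return float(x.mean()), float("nan")
        # anchor on the first value so identical series give exactly 0 spread
        return float(x.mean()), float(2.0 * (x - x.iloc[0]).std(ddof=1))

    per_field = {
        str(fid): mean_2sd(g["t"]) for fid, g in df.groupby("field_id")
    }
    plan_t = df.groupby("fraction")["t"].sum()
    plan_mean, plan_2sd = mean_2sd(plan_t)
    return TimingSummary(
        per_field=per_field,
        plan_mean=plan_mean,
        plan_two_sigma=plan_2sd,
        interlock_free_percent=100.0 * float(df["clean"].mean()),
        n_field_deliveries=len(df),
    )


def timing_table(breakdowns: Sequence[TimingBreakdown]) -> pd.DataFrame:
    """Flat per-field, per-fraction timing table (CSV-friendly)."""
    return pd.DataFrame(
        [
            {
                "field_id": b.field_id,
                "fraction_index": b.fraction_index,
                "drill_s": b.drill_total,
                "spot_switch_s": b.spot_switch_total,
                "energy_switch_s": b.energy_switch_total,
                "interlock_s": b.interlock_total,
                "delivery_time_s": b.delivery_time,
                "had_interlock": b.had_interlock,
            }
            for b in breakdowns
        ]
    )
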