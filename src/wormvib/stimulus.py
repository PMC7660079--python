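"""Before/after-vibration response analysis.

Quantifies vibrotaxis: the response index (fraction of live worms that move
after the stimulus), the complementary no-response ratio, movement amount in
swept px^2 with its mm/s equivalent, and habituation trends against the
cumulative number of stimuli received.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .config import StimulusSchedule

__all__ = [
    "ResponseRecord",
    "MovementSummary",
    "response_index",
    "no_response_ratio",
    "area_to_speed",
    "habituation_trend",
    "build_response_records",
]


@dataclass
class ResponseRecord:
    """Movement outcome of one plate on one day."""

    plate: int
    day: int
    alive: int
    movers_before: int
    movers_after: int | None  # None when no stimulus that day
    t: float = 0.0
    condition: str = ""

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("stimulus duration must be >= 0")
        for m in (self.movers_before, self.movers_after):
            if m is not None and m > self.alive:
                raise ValueError("movers cannot exceed the alive count")


@dataclass
class MovementSummary:
    """Per-day movement amount (motion area, px^2 per 30 s) for one phase."""

    day: int
    phase: str
    mean_area: float
    max_area: float

    def __post_init__(self) -> None:
        if not 0 <= self.mean_area <= self.max_area:
            raise ValueError("require 0 <= mean <= max")


def response_index(record: ResponseRecord) -> float:
    """Fraction of live worms that moved after the stimulus.

    Undefined (NaN) when no live worms remain or the day was unstimulated;
    such records are excluded from aggregates.
    """
    if record.alive <= 0 or record.movers_after is None:
        return math.nan
    return record.movers_after / record.alive


def no_response_ratio(record: ResponseRecord, phase: str = "before") -> float:
    """Fraction of live worms with no detected movement in the given phase."""
    if record.alive <= 0:
        return math.nan
    movers = record.movers_before if phase == "before" else record.movers_after
    if movers is None:
        return math.nan
    return 1.0 - movers / record.alive


def area_to_speed(
    area_px2: float, worm_width_px: float, pixel_scale_um: float, duration_s: float
) -> float:
    """Convert a swept motion area to a linear speed in mm/s.

    A worm of width ``w`` sweeping ``A`` px^2 in ``T`` s has crawled a path of
    length A/w px, i.e. (A/w) * pixel_scale * 1e-3 mm, giving
    ``(A / w) * pixel_scale_um * 1e-3 / T`` mm/s.
    """
    if worm_width_px <= 0 or duration_s <= 0:
        raise ValueError("worm width and duration must be positive")
    if area_px2 < 0:
        raise ValueError("area must be >= 0")
    return (area_px2 / worm_width_px) * pixel_scale_um * 1e-3 / duration_s


def build_response_records(
    truth: pd.DataFrame, schedule: StimulusSchedule, condition: str | None = None
) -> list[ResponseRecord]:
    """Per-plate per-day response records from a ground-truth table.

    The alive denominator excludes occluded worms (they cannot be assessed).
    """
    label = condition if condition is not None else schedule.label
    out = []
    for (plate, day), grp in truth.groupby(["plate", "day"], sort=True):
        vis = grp[grp["alive"] & ~grp["occluded"]]
        t = schedule.duration_on(int(day))
        movers_after = int(vis["moved_after"].eq(True).sum()) if t > 0 else None
        out.append(
            ResponseRecord(
                plate=int(plate),
                day=int(day),
                alive=int(len(vis)),
                movers_before=int(vis["moved_before"].sum()),
                movers_after=movers_after,
                t=t,
                condition=label,
            )
        )
    return out


def habituation_trend(
    records: list[ResponseRecord],
    movement: list[MovementSummary] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Response/movement series against cumulative stimulus count.

    Records are grouped by condition; within each condition, per-day response
    indices (pooled over plates) are laid against the cumulative number of
    stimulation days, and a Kendall tau measures the monotone habituation
    trend (negative tau = habituation). When movement summaries are supplied,
    the per-day mean after-phase motion area is included and its tau returned
    under ``"<condition>:movement"``.
    """
    if not records:
        raise ValueError("no records")
    df = pd.DataFrame(
        [
            {
                "condition": r.condition,
                "day": r.day,
                "alive": r.alive,
                "movers_after": r.movers_after,
                "t": r.t,
            }
            for r in records
        ]
    )
    rows = []
    taus: dict[str, float] = {}
    for cond, grp in df.groupby("condition"):
        stim_days = sorted(grp.loc[grp["t"] > 0, "day"].unique())
        cum = {d: i + 1 for i, d in enumerate(stim_days)}
        per_day = (
            grp[grp["t"] > 0]
            .groupby("day")
            .agg(alive=("alive", "sum"), movers_after=("movers_after", "sum"))
            .reset_index()
        )
        per_day = per_day[per_day["alive"] > 0]
        per_day["response_index"] = per_day["movers_after"] / per_day["alive"]
        per_day["cum_stimuli"] = per_day["day"].map(cum)
        per_day["condition"] = cond
        rows.append(per_day)
        if len(per_day) >= 2 and per_day["response_index"].nunique() > 1:
            tau, _ = kendalltau(per_day["cum_stimuli"], per_day["response_index"])
            taus[str(cond)] = float(tau)
        elif len(per_day) >= 2:
            taus[str(cond)] = 0.0
    trend = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    if movement:
        mv = pd.DataFrame([vars(m) for m in movement])
        mv_after = mv[mv["phase"] == "after"].groupby("day")["mean_area"].mean()
        if len(mv_after) >= 2 and mv_after.nunique() > 1:
            days = sorted(mv_after.index)
            tau, _ = kendalltau(range(len(days)), [mv_after[d] for d in days])
            taus["movement"] = float(tau)
        elif len(mv_after) >= 2:
            taus["movement"] = 0.0
    return trend, taus
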