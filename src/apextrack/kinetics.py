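"""Growth kinetics and geometric measurements derived from track logs.

The closed tracking loop leaves a history of recorded stage positions; the
per-interval growth rate of each root is the chord length between
consecutive tip positions divided by the time step.  Rates can be annotated
with a day/night illumination schedule, and two deterministic image
measurements used in gravistimulation analyses are provided: the root-tip
angle relative to the gravity axis, and the upper/lower fluorescence
intensity ratio across the root axis on a sum projection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import FrameStack
from .session import TrackLog

__all__ = [
    "RatePoint",
    "GrowthSeries",
    "LightSchedule",
    "growth_rates",
    "annotate_light",
    "smooth_rates",
    "tip_angle",
    "sum_project_and_side_ratio",
    "count_membrane_generations",
]


@dataclass(frozen=True)
class RatePoint:
    """One per-interval growth rate, timestamped at the interval midpoint."""

    time_h: float
    rate_um_per_h: float
    light_on: Optional[bool] = None


@dataclass
class GrowthSeries:
    """Ordered per-specimen growth-rate series (µm/h)."""

    rates: dict[str, List[RatePoint]] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "specimen_id": sid,
                "time_h": p.time_h,
                "rate_um_per_h": p.rate_um_per_h,
                "light_on": p.light_on,
            }
            for sid, pts in self.rates.items()
            for p in pts
        ]
        return pd.DataFrame(
            rows, columns=["specimen_id", "time_h", "rate_um_per_h", "light_on"]
        )

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, lineterminator="\n")

    def summary(self) -> pd.DataFrame:
        """Mean rate per specimen per light phase (phase 'all' if unlabeled)."""
        df = self.to_dataframe()
        if df.empty:
            return pd.DataFrame(columns=["specimen_id", "phase", "mean_rate_um_per_h"])
        df = df.copy()
        df["phase"] = df["light_on"].map(
            lambda v: "all" if v is None or (isinstance(v, float) and np.isnan(v))
            else ("on" if v else "off")
        )
        out = (
            df.groupby(["specimen_id", "phase"], sort=True)["rate_um_per_h"]
            .mean()
            .reset_index()
            .rename(columns={"rate_um_per_h": "mean_rate_um_per_h"})
        )
        return out


@dataclass(frozen=True)
class LightInterval:
    start_h: float
    end_h: float
    on: bool


@dataclass
class LightSchedule:
    """Non-overlapping illumination intervals covering the session span."""

    intervals: List[LightInterval]

    def __post_init__(self) -> None:
        iv = sorted(self.intervals, key=lambda i: i.start_h)
        for a, b in zip(iv, iv[1:]):
            if b.start_h < a.end_h:
                raise ValueError("light schedule intervals overlap")
        self.intervals = iv

    @classmethod
    def cycle(
        cls, on_h: float, off_h: float, span_h: float, start_on: bool = True
    ) -> "LightSchedule":
        """Periodic schedule, e.g. 16 h on / 8 h off, covering ``span_h``."""
        iv, t, on = [], 0.0, start_on
        while t < span_h:
            dur = on_h if on else off_h
            iv.append(LightInterval(t, min(t + dur, span_h) if t + dur >= span_h else t + dur, on))
            t += dur
            on = not on
        return cls(iv)

    def is_on(self, time_h: float) -> bool:
        """State at ``time_h``; intervals are half-open [start, end)."""
        for iv in self.intervals:
            if iv.start_h <= time_h < iv.end_h:
                return iv.on
        raise ValueError(f"time {time_h} h is not covered by the light schedule")

    @classmethod
    def load_csv(cls, path) -> "LightSchedule":
        df = pd.read_csv(path)
        return cls(
            [
                LightInterval(float(r["start_h"]), float(r["end_h"]), bool(r["on"]))
                for _, r in df.iterrows()
            ]
        )


def growth_rates(log: TrackLog) -> GrowthSeries:
    """Per-interval growth rates from the history of recorded positions.

    Rate between consecutive records = Euclidean distance of stage positions
    (µm) / elapsed time (h), timestamped at the interval midpoint.  Intervals
    in which the specimen was stopped are excluded; a single-record specimen
    yields an empty series.
    """
    series = GrowthSeries()
    for sid in log.specimens():
        recs = log.for_specimen(sid)
        pts: List[RatePoint] = []
        for a, b in zip(recs, recs[1:]):
            if not (a.active and b.active):
                continue
            dt = b.time_h - a.time_h
            if dt <= 0:
                raise ValueError(f"non-increasing time for specimen '{sid}'")
            dist = math.hypot(b.x_um - a.x_um, b.y_um - a.y_um)
            pts.append(RatePoint((a.time_h + b.time_h) / 2.0, dist / dt))
        series.rates[sid] = pts
    return series


def annotate_light(series: GrowthSeries, schedule: LightSchedule) -> GrowthSeries:
    """Label each rate entry by the illumination state at its midpoint time."""
    out = GrowthSeries()
    for sid, pts in series.rates.items():
        out.rates[sid] = [
            RatePoint(p.time_h, p.rate_um_per_h, schedule.is_on(p.time_h)) for p in pts
        ]
    return out


def smooth_rates(series: GrowthSeries, window: int = 3) -> GrowthSeries:
    """Optional centered moving average of the rate series (odd window)."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    out = GrowthSeries()
    half = window // 2
    for sid, pts in series.rates.items():
        vals = [p.rate_um_per_h for p in pts]
        sm = []
        for i, p in enumerate(pts):
            lo, hi = max(0, i - half), min(len(vals), i + half + 1)
            sm.append(RatePoint(p.time_h, float(np.mean(vals[lo:hi])), p.light_on))
        out.rates[sid] = sm
    return out


def tip_angle(tip: Tuple[float, float], organizing_centre: Tuple[float, float]) -> float:
    """Angle of the organizing-centre→tip vector from the gravity axis.

    The gravity axis is image +y (downward); 0° means growing straight down,
    clockwise angles are positive, range (−180°, 180°].
    """
    vx = tip[0] - organizing_centre[0]
    vy = tip[1] - organizing_centre[1]
    if vx == 0.0 and vy == 0.0:
        raise ValueError("tip and organizing centre coincide; angle undefined")
    return math.degrees(math.atan2(vx, vy))


def sum_project_and_side_ratio(
    stack: FrameStack,
    axis_point_px: Tuple[float, float],
    axis_angle_deg: float,
    box_px: Tuple[int, int],
    gap_px: float = 0.0,
    channel: int = 0,
) -> Tuple[float, float, float]:
    """Mean intensity in two congruent boxes mirrored across the root axis.

    The stack is sum-projected over z.  The axis is the oriented line through
    ``axis_point_px`` (col, row) at ``axis_angle_deg`` from image +y
    (clockwise positive, like :func:`tip_angle`).  Two ``box_px`` = (length
    along axis, width across axis) rectangles are placed symmetrically,
    separated by ``gap_px`` across the axis; "upper" is the side to the left
    of the oriented axis (toward −y for a horizontal axis pointing +x).

    Returns (upper_mean, lower_mean, upper/lower ratio).
    """
    if not (0 <= channel < stack.n_channels):
        raise IndexError(f"channel {channel} does not exist")
    proj = stack.intensities[channel].sum(axis=0, dtype=np.float64)
    h, w = proj.shape
    length, width = box_px
    theta = math.radians(axis_angle_deg)
    ux, uy = math.sin(theta), math.cos(theta)  # along axis
    nx, ny = uy, -ux  # normal, "upper" side
    px0, py0 = axis_point_px

    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    s = (cols - px0) * ux + (rows - py0) * uy
    r = (cols - px0) * nx + (rows - py0) * ny

    def box_mask(r_lo: float, r_hi: float) -> np.ndarray:
        corners_r = [r_lo, r_hi]
        for cr in corners_r:
            for cs in (0.0, float(length)):
                cx = px0 + cs * ux + cr * nx
                cy = py0 + cs * uy + cr * ny
                if not (0 <= cx <= w - 1 and 0 <= cy <= h - 1):
                    raise ValueError("measurement box extends outside the image")
        return (s >= 0) & (s < length) & (r >= r_lo) & (r < r_hi)

    upper = box_mask(gap_px / 2.0, gap_px / 2.0 + width)
    lower = box_mask(-gap_px / 2.0 - width, -gap_px / 2.0)
    upper_mean = float(proj[upper].mean())
    lower_mean = float(proj[lower].mean())
    return upper_mean, lower_mean, upper_mean / lower_mean


def count_membrane_generations(world, t0: float, t1: float) -> List[int]:
    """New cross-walls between adjacent first-generation walls of a cell file.

    For each pair of walls adjacent at ``t0``, counts the walls created in
    (t0, t1] lying strictly between them.  After k synchronized division
    rounds every pair separates 2^k − 1 new walls (two rounds → 3).
    """
    walls = world.walls_at(t1)  # (arc position, creation time), any order
    first_gen = sorted(s for s, created in walls if created <= t0)
    new = [(s, c) for s, c in walls if t0 < c <= t1]
    counts = []
    for lo, hi in zip(first_gen, first_gen[1:]):
        counts.append(sum(1 for s, _ in new if lo < s < hi))
    return counts
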