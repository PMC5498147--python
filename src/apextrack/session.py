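"""Closed-loop tracking session over a microscope interface.

Each cycle acquires one stack per active specimen at the current stage
positions, estimates the lateral shift against the previous time point,
updates the cumulative displacement, applies the safety limit, predicts the
next positions and loads them into the (real or simulated) microscope.  The
position list is persisted after every time point so a crashed session can
be resumed from disk.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

from .core import (
    Displacement,
    FrameStack,
    LateralShift,
    TrackerConfig,
    ZeroVarianceError,
    crop_roi,
    max_intensity_project,
    predict_positions,
    robust_shift,
    update_displacement,
)

__all__ = [
    "StagePosition",
    "StopReason",
    "TrackRecord",
    "TrackLog",
    "MicroscopeInterface",
    "AcquisitionError",
    "check_safety_limit",
    "imaging_cycle_count",
    "run_session",
    "save_positions",
    "load_positions",
]

POSITION_COLUMNS = ["specimen_id", "x_um", "y_um", "z_um", "active"]
LOG_COLUMNS = [
    "time_index",
    "time_h",
    "specimen_id",
    "x_um",
    "y_um",
    "dx_px",
    "dy_px",
    "delta_x_um",
    "delta_y_um",
    "active",
    "stop_reason",
]


class AcquisitionError(RuntimeError):
    """Raised by a microscope when an acquisition fails."""


class StopReason(str, enum.Enum):
    NONE = "none"
    SAFETY_LIMIT = "safety_limit"
    ZERO_VARIANCE = "zero_variance"
    USER = "user"


@dataclass(frozen=True)
class StagePosition:
    """Stage coordinates (µm) of one specimen; z is optional pass-through."""

    specimen_id: str
    x_um: float
    y_um: float
    z_um: Optional[float] = None
    active: bool = True

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x_um) and math.isfinite(self.y_um)):
            raise ValueError(f"non-finite coordinates for '{self.specimen_id}'")
        if self.z_um is not None and not math.isfinite(self.z_um):
            raise ValueError(f"non-finite z for '{self.specimen_id}'")


def _check_unique_ids(positions: Sequence[StagePosition]) -> None:
    ids = [p.specimen_id for p in positions]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate specimen_id(s): {dupes}")


@dataclass(frozen=True)
class TrackRecord:
    time_index: int
    time_h: float
    specimen_id: str
    x_um: float
    y_um: float
    dx_px: Optional[float]  # None at time_index 0 and for stopped specimens
    dy_px: Optional[float]
    delta_x_um: Optional[float]
    delta_y_um: Optional[float]
    active: bool
    stop_reason: StopReason = StopReason.NONE


@dataclass
class TrackLog:
    """Per-specimen time series of positions, shifts and displacements."""

    records: List[TrackRecord] = field(default_factory=list)

    def append(self, rec: TrackRecord) -> None:
        prev = [r for r in self.records if r.specimen_id == rec.specimen_id]
        if prev:
            if rec.time_index <= prev[-1].time_index:
                raise ValueError("time_index must be strictly increasing per specimen")
            if not prev[-1].active and rec.active:
                raise ValueError("a stopped specimen cannot become active again")
        if rec.time_index == 0 and rec.delta_x_um is not None:
            raise ValueError("displacement entries must be absent at time_index 0")
        self.records.append(rec)

    def specimens(self) -> List[str]:
        seen: Dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.specimen_id, None)
        return list(seen)

    def for_specimen(self, specimen_id: str) -> List[TrackRecord]:
        return [r for r in self.records if r.specimen_id == specimen_id]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "time_index": r.time_index,
                    "time_h": r.time_h,
                    "specimen_id": r.specimen_id,
                    "x_um": r.x_um,
                    "y_um": r.y_um,
                    "dx_px": r.dx_px,
                    "dy_px": r.dy_px,
                    "delta_x_um": r.delta_x_um,
                    "delta_y_um": r.delta_y_um,
                    "active": r.active,
                    "stop_reason": r.stop_reason.value,
                }
            )
        return pd.DataFrame(rows, columns=LOG_COLUMNS)

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def load_csv(cls, path) -> "TrackLog":
        df = pd.read_csv(path, float_precision="round_trip")
        missing = set(LOG_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"track log {path} missing columns: {sorted(missing)}")
        log = cls()
        for _, row in df.iterrows():

            def opt(v):
                return None if pd.isna(v) else float(v)

            log.append(
                TrackRecord(
                    time_index=int(row["time_index"]),
                    time_h=float(row["time_h"]),
                    specimen_id=str(row["specimen_id"]),
                    x_um=float(row["x_um"]),
                    y_um=float(row["y_um"]),
                    dx_px=opt(row["dx_px"]),
                    dy_px=opt(row["dy_px"]),
                    delta_x_um=opt(row["delta_x_um"]),
                    delta_y_um=opt(row["delta_y_um"]),
                    active=bool(row["active"]),
                    stop_reason=StopReason(row["stop_reason"]),
                )
            )
        return log


@runtime_checkable
class MicroscopeInterface(Protocol):
    """Contract a stage/scanhead driver must satisfy.

    Acquisition at a time point uses exactly the last position list loaded.
    """

    @property
    def pixel_size(self) -> float: ...

    @property
    def frame_shape(self) -> tuple[int, int]: ...

    def load_position_list(self, positions: Sequence[StagePosition]) -> None: ...

    def acquire(self, time_index: int, time_h: float) -> Dict[str, FrameStack]: ...


def check_safety_limit(displacement: Displacement, config: TrackerConfig) -> bool:
    """True iff the Euclidean norm of the per-step move is within the limit.

    The comparison is inclusive: a move of exactly ``max_step_um`` passes.
    """
    return displacement.norm() <= config.max_step_um


def imaging_cycle_count(span_h: float, interval_h: float) -> int:
    """Number of imaging cycles over a session span, counting both endpoints.

    A span of 38 h 20 min imaged every 20 min comprises 116 cycles.
    """
    if interval_h <= 0:
        raise ValueError("interval must be > 0")
    return int(math.floor(span_h / interval_h + 1e-9)) + 1


def save_positions(positions: Sequence[StagePosition], path) -> None:
    """Write a position list CSV (lossless full-precision round trip)."""
    _check_unique_ids(positions)
    rows = [
        {
            "specimen_id": p.specimen_id,
            "x_um": repr(p.x_um),
            "y_um": repr(p.y_um),
            "z_um": "" if p.z_um is None else repr(p.z_um),
            "active": p.active,
        }
        for p in positions
    ]
    df = pd.DataFrame(rows, columns=POSITION_COLUMNS)
    df.to_csv(path, index=False, lineterminator="\n")


def load_positions(path) -> List[StagePosition]:
    path = Path(path)
    df = pd.read_csv(path, dtype={"specimen_id": str}, float_precision="round_trip")
    missing = set(POSITION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"position list {path} missing columns: {sorted(missing)}")
    positions = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            z = row["z_um"]
            positions.append(
                StagePosition(
                    specimen_id=str(row["specimen_id"]),
                    x_um=float(row["x_um"]),
                    y_um=float(row["y_um"]),
                    z_um=None if pd.isna(z) else float(z),
                    active=bool(row["active"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed value at line {line}: {exc}") from exc
    try:
        _check_unique_ids(positions)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    return positions


def run_session(
    microscope: MicroscopeInterface,
    initial: Sequence[StagePosition],
    config: TrackerConfig,
    n_timepoints: int,
    interval_h: float,
    out_dir=None,
) -> TrackLog:
    """Run the closed tracking loop for ``n_timepoints`` acquisitions.

    At t = 0 each specimen is only acquired (no predecessor to correlate
    against; δ starts at zero, so the first inter-frame interval is
    uncompensated).  From t = 1 on, the median-of-three shift against t − 1
    updates δ, the safety limit is checked, and the predicted positions
    P + δ are loaded for the next acquisition.  A specimen stopped by the
    safety limit (or by a blank, zero-variance frame) keeps its last
    position; the others continue.  If ``out_dir`` is given, the current
    position list and the partial track log are written after every time
    point, and preserved if an acquisition fails mid-session.
    """
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be >= 1")
    _check_unique_ids(initial)
    if not all(p.active for p in initial):
        raise ValueError("all initial positions must be active")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    positions = list(initial)
    displacements: Dict[str, Displacement] = {
        p.specimen_id: Displacement.zero() for p in positions
    }
    stop_reasons: Dict[str, StopReason] = {
        p.specimen_id: StopReason.NONE for p in positions
    }
    prev_roi: Dict[str, np.ndarray] = {}
    log = TrackLog()
    px = microscope.pixel_size

    def persist() -> None:
        if out_dir is not None:
            save_positions(positions, out_dir / "positions.csv")
            log.save_csv(out_dir / "track_log.csv")

    for t in range(n_timepoints):
        time_h = t * interval_h
        microscope.load_position_list(positions)
        try:
            stacks = microscope.acquire(t, time_h)
        except AcquisitionError:
            persist()
            raise

        new_positions: List[StagePosition] = []
        for pos in positions:
            sid = pos.specimen_id
            if not pos.active:
                log.append(
                    TrackRecord(
                        t, time_h, sid, pos.x_um, pos.y_um, None, None,
                        None, None, False, stop_reasons[sid],
                    )
                )
                new_positions.append(pos)
                continue

            stack = stacks[sid]
            roi = crop_roi(
                max_intensity_project(stack, config.tracking_channel),
                config.roi_fraction,
            )
            shift: Optional[LateralShift] = None
            active = True
            if t > 0:
                try:
                    shift = robust_shift(prev_roi[sid], roi, config)
                except ZeroVarianceError:
                    active = False
                    stop_reasons[sid] = StopReason.ZERO_VARIANCE
                if shift is not None:
                    delta = update_displacement(
                        displacements[sid], shift, px, config.axis_map
                    )
                    if check_safety_limit(delta, config):
                        displacements[sid] = delta
                    else:
                        active = False
                        stop_reasons[sid] = StopReason.SAFETY_LIMIT
                        displacements[sid] = delta  # recorded, never applied

            d = displacements[sid]
            log.append(
                TrackRecord(
                    t, time_h, sid, pos.x_um, pos.y_um,
                    shift.dx_px if shift is not None else None,
                    shift.dy_px if shift is not None else None,
                    d.dx_um if t > 0 else None,
                    d.dy_um if t > 0 else None,
                    active, stop_reasons[sid],
                )
            )
            prev_roi[sid] = roi
            new_positions.append(pos if active else replace(pos, active=False))

        active_disp = {
            p.specimen_id: displacements[p.specimen_id]
            for p in new_positions
            if p.active
        }
        positions = predict_positions(new_positions, active_disp)
        persist()

    return log
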