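"""TIFF stack I/O and per-position hyperstack splitting.

Acquisition writes one multi-page TIFF per time point containing the
multi-position, multi-channel z-stacks of that cycle, with hyperstack
dimension order position → channel → z → row → col (axes ``PCZYX``).  For
per-specimen analysis these files are converted into one hyperstack per
position, ordered time → channel → z → row → col (axes ``TCZYX``).  All
metadata (pixel size, times, specimen ids) travels in a JSON image
description; intensities are 16-bit unsigned (8-bit accepted on read) and
round trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import tifffile

from .core import FrameStack

__all__ = [
    "write_timepoint",
    "read_timepoint",
    "split_by_position",
    "read_hyperstack",
]


def write_timepoint(stacks: Sequence[FrameStack], path) -> None:
    """Write one time point's stacks (all positions) to a multi-page TIFF."""
    if not stacks:
        raise ValueError("no stacks to write")
    shapes = {s.intensities.shape for s in stacks}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent stack dimensions across positions: {shapes}")
    if len({s.pixel_size for s in stacks}) != 1:
        raise ValueError("inconsistent pixel sizes across positions")
    arr = np.stack([np.asarray(s.intensities, dtype=np.uint16) for s in stacks])
    meta = {
        "axes": "PCZYX",
        "shape": list(arr.shape),
        "pixel_size_um": stacks[0].pixel_size,
        "time_index": stacks[0].time_index,
        "time_h": stacks[0].time_h,
        "specimen_ids": [s.specimen_id for s in stacks],
    }
    tifffile.imwrite(
        Path(path),
        arr.reshape(-1, arr.shape[-2], arr.shape[-1]),
        photometric="minisblack",
        description=json.dumps(meta, sort_keys=True),
    )


def _read_described(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            desc = tif.pages[0].description
            data = tif.asarray()
    except (tifffile.TiffFileError, FileNotFoundError, OSError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    try:
        meta = json.loads(desc)
    except (TypeError, json.JSONDecodeError) as exc:
        raise ValueError(f"{path}: missing or malformed stack metadata") from exc
    if data.dtype == np.uint8:
        data = data.astype(np.uint16)
    return data.reshape(meta["shape"]), meta


def read_timepoint(path) -> List[FrameStack]:
    """Read a per-time-point multi-position TIFF back into FrameStacks."""
    data, meta = _read_described(path)
    if meta.get("axes") != "PCZYX":
        raise ValueError(f"{path}: expected PCZYX time-point file, got {meta.get('axes')}")
    return [
        FrameStack(
            intensities=data[i],
            pixel_size=meta["pixel_size_um"],
            time_index=meta["time_index"],
            time_h=meta["time_h"],
            specimen_id=meta["specimen_ids"][i],
        )
        for i in range(data.shape[0])
    ]


def split_by_position(timepoint_files: Sequence, out_dir) -> Dict[str, Path]:
    """Convert per-time-point multi-position files into per-position hyperstacks.

    Every input file must contain the same positions in the same order.
    Output: one ``TCZYX`` TIFF per position under ``out_dir``; voxel data is
    bit-identical to the sources, time order follows the input file order.
    Returns a mapping specimen_id → written path.
    """
    if not timepoint_files:
        raise ValueError("no time-point files given")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    per_file = []
    ref_ids = None
    for f in timepoint_files:
        data, meta = _read_described(f)
        ids = meta["specimen_ids"]
        if ref_ids is None:
            ref_ids = ids
        elif ids != ref_ids:
            raise ValueError(
                f"{f}: position set {ids} differs from first file's {ref_ids}"
            )
        per_file.append((data, meta))

    written: Dict[str, Path] = {}
    for i, sid in enumerate(ref_ids):
        hyper = np.stack([data[i] for data, _ in per_file])  # (T, C, Z, Y, X)
        meta = {
            "axes": "TCZYX",
            "shape": list(hyper.shape),
            "pixel_size_um": per_file[0][1]["pixel_size_um"],
            "specimen_id": sid,
            "time_indices": [m["time_index"] for _, m in per_file],
            "time_h": [m["time_h"] for _, m in per_file],
        }
        path = out_dir / f"{sid}.tif"
        tifffile.imwrite(
            path,
            hyper.reshape(-1, hyper.shape[-2], hyper.shape[-1]),
            photometric="minisblack",
            description=json.dumps(meta, sort_keys=True),
        )
        written[sid] = path
    return written


def read_hyperstack(path) -> tuple[np.ndarray, dict]:
    """Read a per-position TCZYX hyperstack; returns (array, metadata)."""
    data, meta = _read_described(path)
    if meta.get("axes") != "TCZYX":
        raise ValueError(f"{path}: expected TCZYX hyperstack, got {meta.get('axes')}")
    return data, meta
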