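"""Recomputing stage positions after rotating the sample chamber.

For gravistimulation experiments the sample chamber is rotated by an
arbitrary angle about a mechanical centre of rotation.  The centre is
calibrated once by imaging a small drilled hole that coincides with it;
afterwards, specimen positions recorded before a rotation are mapped to
their post-rotation stage coordinates with a rigid 2-D rotation, so imaging
can resume within minutes without manually re-finding every specimen.

Angle convention: positive = clockwise as seen in the displayed image.
With image rows increasing downward this is the mathematically positive
rotation in (x, y-down) stage coordinates: (x, y) → (x·cosθ − y·sinθ,
x·sinθ + y·cosθ) relative to the centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import AxisMap
from .session import StagePosition

__all__ = [
    "RotationCalibration",
    "locate_calibration_hole",
    "rotate_positions",
    "save_calibration",
    "load_calibration",
]


@dataclass(frozen=True)
class RotationCalibration:
    """Stage coordinates (µm) of the mechanical centre of rotation."""

    centre_x_um: float
    centre_y_um: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.centre_x_um) and math.isfinite(self.centre_y_um)):
            raise ValueError("calibration centre must be finite")


def save_calibration(calib: RotationCalibration, path) -> None:
    pd.DataFrame(
        [{"centre_x_um": repr(calib.centre_x_um), "centre_y_um": repr(calib.centre_y_um)}]
    ).to_csv(path, index=False, lineterminator="\n")


def load_calibration(path) -> RotationCalibration:
    df = pd.read_csv(path)
    row = df.iloc[0]
    return RotationCalibration(float(row["centre_x_um"]), float(row["centre_y_um"]))


def locate_calibration_hole(
    image: np.ndarray,
    pixel_size: float,
    stage_pos: StagePosition,
    axis_map: AxisMap | None = None,
) -> RotationCalibration:
    """Stage coordinates of the single bright disk marking the rotation centre.

    The image is thresholded at its inter-modal (Otsu) level; exactly one
    connected bright region must remain.  The calibration point is the
    region's intensity centroid mapped to stage coordinates:
    stage_pos + (centroid − frame centre)·pixel_size.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.std() == 0.0:
        raise ValueError("no calibration disk found: image has no contrast (0 candidates)")
    mask = img > threshold_otsu(img)
    labels, n = ndimage.label(mask)
    if n != 1:
        raise ValueError(f"expected exactly one calibration disk, found {n} candidate(s)")
    # intensity centroid of the bright region
    r_c, c_c = ndimage.center_of_mass(img * mask)
    h, w = img.shape
    off_col = c_c - (w - 1) / 2.0
    off_row = r_c - (h - 1) / 2.0
    axis_map = axis_map or AxisMap()
    off_x, off_y = axis_map.to_stage(off_col, off_row)
    return RotationCalibration(
        centre_x_um=stage_pos.x_um + off_x * pixel_size,
        centre_y_um=stage_pos.y_um + off_y * pixel_size,
    )


def rotate_positions(
    positions: Sequence[StagePosition],
    calib: RotationCalibration,
    angle_deg: float,
) -> List[StagePosition]:
    """Map each position P to C + R(angle)·(P − C) about the calibrated centre.

    Positive angles are clockwise in the displayed image (y-down convention).
    z and the active flag pass through unchanged; order is preserved.
    """
    theta = math.radians(angle_deg)
    c, s = math.cos(theta), math.sin(theta)
    cx, cy = calib.centre_x_um, calib.centre_y_um
    out = []
    for p in positions:
        vx, vy = p.x_um - cx, p.y_um - cy
        out.append(
            replace(p, x_um=cx + c * vx - s * vy, y_um=cy + s * vx + c * vy)
        )
    return out
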