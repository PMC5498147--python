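"""Per-time-point tracking computation.

The tracking cycle for one specimen and one time step is:

1. maximum-intensity projection of the z-stack in the tracking channel,
2. centered region-of-interest crop (default one third of the frame),
3. three filter variants of the ROI (raw, mean-filtered, median-filtered),
4. direct cross-correlation of each variant pair against the previous time
   point, yielding three candidate lateral shifts,
5. component-wise median of the three shifts (robust fusion),
6. displacement update δ(t) = δ(t−1) + Δ·pixel_size, mapped from image axes
   to stage axes,
7. position prediction P(t+1) = P(t) + δ(t).

All image-frame quantities are in pixels; stage-frame quantities are in µm.
Image axes are row-down/col-right, 0-based; the default axis map sends image
col → stage +x and image row → stage +y.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "FrameStack",
    "LateralShift",
    "Displacement",
    "AxisMap",
    "TrackerConfig",
    "ZeroVarianceError",
    "max_intensity_project",
    "crop_roi",
    "filter_variants",
    "correlation_surface",
    "xcorr_shift",
    "robust_shift",
    "update_displacement",
    "predict_positions",
]


class ZeroVarianceError(ValueError):
    """Raised when a frame has no intensity variance and cannot be tracked."""


@dataclass(frozen=True)
class LateralShift:
    """Per-step image shift Δ in pixels (col direction dx, row direction dy)."""

    dx_px: float
    dy_px: float

    def __iter__(self):
        yield self.dx_px
        yield self.dy_px


@dataclass(frozen=True)
class Displacement:
    """Cumulative per-interval stage displacement δ in µm."""

    dx_um: float
    dy_um: float

    def norm(self) -> float:
        return float(np.hypot(self.dx_um, self.dy_um))

    @staticmethod
    def zero() -> "Displacement":
        return Displacement(0.0, 0.0)


@dataclass(frozen=True)
class AxisMap:
    """Relates image axes (col, row) to stage axes (x, y).

    Hardware dependent: microscopes differ in stage-axis orientation relative
    to the camera.  ``swap_xy`` exchanges the axes before the signs are
    applied.  The identity map sends image col → stage +x, image row → +y.
    """

    sign_x: int = 1
    sign_y: int = 1
    swap_xy: bool = False

    def __post_init__(self) -> None:
        if self.sign_x not in (-1, 1) or self.sign_y not in (-1, 1):
            raise ValueError("axis signs must be +1 or -1")

    def to_stage(self, dx_px: float, dy_px: float) -> tuple[float, float]:
        if self.swap_xy:
            dx_px, dy_px = dy_px, dx_px
        return self.sign_x * dx_px, self.sign_y * dy_px


@dataclass
class FrameStack:
    """One specimen's multi-channel z-stack at one time point.

    ``intensities`` is indexed (channel, z, row, col); non-negative.
    """

    intensities: np.ndarray
    pixel_size: float
    time_index: int
    time_h: float
    specimen_id: str

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 4:
            raise ValueError(
                f"intensities must be 4-D (channel, z, row, col), got {arr.ndim}-D"
            )
        if any(s < 1 for s in arr.shape):
            raise ValueError(f"all stack dimensions must be >= 1, got {arr.shape}")
        if np.any(arr < 0):
            raise ValueError("intensities must be non-negative")
        if not (np.isfinite(self.pixel_size) and self.pixel_size > 0):
            raise ValueError(f"pixel_size must be finite and > 0, got {self.pixel_size}")
        if self.time_index < 0 or self.time_h < 0:
            raise ValueError("time_index and time_h must be non-negative")
        self.intensities = arr

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_z(self) -> int:
        return self.intensities.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.intensities.shape[2], self.intensities.shape[3]


@dataclass(frozen=True)
class TrackerConfig:
    """Tunable parameters of the tracking cycle.

    roi_fraction
        Side of the centered tracking window as a fraction of the smaller
        frame dimension.  Default 1/3: with a 20x field of view of ~640 µm
        this gives a ~213 µm window, large enough that a root growing at up
        to 300 µm/h stays inside it between acquisitions at ≤30-min
        intervals.
    mean_kernel_px, median_kernel_px
        Odd kernel sizes of the two filter variants.
    max_step_um
        Safety limit on the per-step stage move; a specimen whose commanded
        move would exceed it is stopped (objective protection).
    """

    roi_fraction: float = 1.0 / 3.0
    mean_kernel_px: int = 3
    median_kernel_px: int = 3
    max_step_um: float = 200.0
    tracking_channel: int = 0
    subpixel: bool = False
    axis_map: AxisMap = field(default_factory=AxisMap)

    def __post_init__(self) -> None:
        if not (0.0 < self.roi_fraction <= 1.0):
            raise ValueError(f"roi_fraction must be in (0, 1], got {self.roi_fraction}")
        for name in ("mean_kernel_px", "median_kernel_px"):
            k = getattr(self, name)
            if k < 1 or k % 2 == 0:
                raise ValueError(f"{name} must be an odd integer >= 1, got {k}")
        if not self.max_step_um > 0:
            raise ValueError(f"max_step_um must be > 0, got {self.max_step_um}")

    def with_(self, **kwargs) -> "TrackerConfig":
        return replace(self, **kwargs)


def max_intensity_project(stack: FrameStack, channel: int) -> np.ndarray:
    """Maximum-intensity projection over z of one channel.

    Output pixel (r, c) is the maximum over z of the input (channel, z, r, c).
    """
    if not (0 <= channel < stack.n_channels):
        raise IndexError(
            f"channel {channel} does not exist in stack "
            f"'{stack.specimen_id}' with {stack.n_channels} channel(s)"
        )
    return stack.intensities[channel].max(axis=0)


def crop_roi(image: np.ndarray, roi_fraction: float) -> np.ndarray:
    """Centered square crop of side floor(roi_fraction * min(h, w)), >= 1."""
    if not (0.0 < roi_fraction <= 1.0):
        raise ValueError(f"roi_fraction must be in (0, 1], got {roi_fraction}")
    h, w = image.shape[-2], image.shape[-1]
    side = max(1, int(np.floor(roi_fraction * min(h, w))))
    r0 = (h - side) // 2
    c0 = (w - side) // 2
    return image[..., r0 : r0 + side, c0 : c0 + side]


def filter_variants(
    image: np.ndarray, config: TrackerConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw, moving-average and moving-median variants of an image.

    Borders are handled by edge replication, which avoids spurious dark
    borders that would bias the correlation peak.
    """
    for name, k in (("mean", config.mean_kernel_px), ("median", config.median_kernel_px)):
        if k % 2 == 0:
            raise ValueError(f"{name} kernel must be odd, got {k}")
    img = np.asarray(image, dtype=np.float64)
    mean_f = ndimage.uniform_filter(img, size=config.mean_kernel_px, mode="nearest")
    median_f = ndimage.median_filter(img, size=config.median_kernel_px, mode="nearest")
    return img, mean_f, median_f


def correlation_surface(ref: np.ndarray, cur: np.ndarray) -> np.ndarray:
    """Direct cross-correlation of the mean-subtracted images over all lags.

    Entry (i, j) is the correlation at lag (dy, dx) = (i − h + 1, j − w + 1);
    the surface peaks at the lag by which ``cur`` content is moved relative
    to ``ref``.  No amplitude normalization is applied.
    """
    if ref.shape != cur.shape:
        raise ValueError(f"image dimensions differ: {ref.shape} vs {cur.shape}")
    a = np.asarray(cur, dtype=np.float64)
    b = np.asarray(ref, dtype=np.float64)
    if a.std() == 0.0 or b.std() == 0.0:
        raise ZeroVarianceError("zero-variance image: frame is untrackable")
    a = a - a.mean()
    b = b - b.mean()
    # c(dy, dx) = sum over overlap of cur[r, c] * ref[r - dy, c - dx]
    return signal.correlate(a, b, mode="full", method="fft")


def _parabolic_offset(cm: float, c0: float, cp: float) -> float:
    denom = cm - 2.0 * c0 + cp
    if denom >= 0.0:  # not a strict maximum; no refinement possible
        return 0.0
    off = 0.5 * (cm - cp) / denom
    return float(np.clip(off, -0.5, 0.5))


def xcorr_shift(ref: np.ndarray, cur: np.ndarray, subpixel: bool = False) -> LateralShift:
    """Lateral shift Δ maximizing the direct cross-correlation of ref and cur.

    Sign convention: ``cur`` content is moved by +Δ relative to ``ref``, so
    applying the returned shift to ``ref`` aligns it onto ``cur``.  Ties at
    the peak are broken toward the smaller shift magnitude, then toward
    non-negative dx, then non-negative dy.  With ``subpixel`` the integer
    peak is refined by parabolic interpolation using its 4 neighbors.
    """
    surf = correlation_surface(ref, cur)
    h, w = ref.shape
    peak = surf.max()
    cand = np.argwhere(surf == peak)
    lags = cand - np.array([h - 1, w - 1])  # rows: (dy, dx)
    order = sorted(
        range(len(lags)),
        key=lambda i: (
            lags[i, 0] ** 2 + lags[i, 1] ** 2,
            lags[i, 1] < 0,
            lags[i, 0] < 0,
        ),
    )
    iy, ix = cand[order[0]]
    dy = float(iy - (h - 1))
    dx = float(ix - (w - 1))
    if subpixel:
        if 0 < iy < surf.shape[0] - 1:
            dy += _parabolic_offset(surf[iy - 1, ix], surf[iy, ix], surf[iy + 1, ix])
        if 0 < ix < surf.shape[1] - 1:
            dx += _parabolic_offset(surf[iy, ix - 1], surf[iy, ix], surf[iy, ix + 1])
    return LateralShift(dx_px=dx, dy_px=dy)


def robust_shift(ref: np.ndarray, cur: np.ndarray, config: TrackerConfig) -> LateralShift:
    """Median-of-three shift: correlate raw, mean- and median-filtered pairs.

    The component-wise median of the three variant shifts makes the estimate
    robust against impulsive noise that may derail any single variant.
    """
    ref_variants = filter_variants(ref, config)
    cur_variants = filter_variants(cur, config)
    shifts = [
        xcorr_shift(r, c, subpixel=config.subpixel)
        for r, c in zip(ref_variants, cur_variants)
    ]
    dx = float(np.median([s.dx_px for s in shifts]))
    dy = float(np.median([s.dy_px for s in shifts]))
    return LateralShift(dx_px=dx, dy_px=dy)


def update_displacement(
    prev: Displacement,
    shift: LateralShift,
    pixel_size: float,
    axis_map: AxisMap | None = None,
) -> Displacement:
    """δ(t) = δ(t−1) + Δ·pixel_size, with Δ mapped to stage axes."""
    if not pixel_size > 0:
        raise ValueError(f"pixel_size must be > 0, got {pixel_size}")
    axis_map = axis_map or AxisMap()
    sx, sy = axis_map.to_stage(shift.dx_px, shift.dy_px)
    return Displacement(prev.dx_um + sx * pixel_size, prev.dy_um + sy * pixel_size)


def predict_positions(positions: Sequence, displacements: Mapping[str, Displacement]):
    """P(Tn+1) = P(Tn) + δ for active specimens; inactive kept verbatim.

    ``positions`` is a sequence of StagePosition-like objects with fields
    specimen_id, x_um, y_um, z_um, active; z passes through unchanged.
    """
    out = []
    for pos in positions:
        if not pos.active:
            out.append(pos)
            continue
        if pos.specimen_id not in displacements:
            raise KeyError(
                f"no displacement entry for active specimen '{pos.specimen_id}'"
            )
        d = displacements[pos.specimen_id]
        out.append(replace(pos, x_um=pos.x_um + d.dx_um, y_um=pos.y_um + d.dy_um))
    return out
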