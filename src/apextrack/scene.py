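"""Synthetic specimens and a simulated microscope stage.

Two continuous-coordinate world models are provided so the whole tracking
system can be exercised end-to-end with no external data:

* a growing root tip — a bright-walled tube (membrane-marker-like
  appearance) advancing along the gravity axis at 50–300 µm/h, optionally
  with day/night speed modulation, gravitropic re-bending after a chamber
  rotation, and a 1-D cell file whose cells divide periodically, inserting
  new cross-walls at cell midpoints;
* a migrating cell cluster (zebrafish-prechordal-plate-like) — overlapping
  soft disks jittering about a moving centroid.

Worlds live in continuous µm coordinates and can be rendered at any stage
window, pixel size and time; every ground-truth quantity (tip position,
wall ledger, cluster centroid) is available exactly, so renders double as
an oracle for the tracker.  All randomness flows from a single seed; equal
seeds give bit-identical output.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage

from .core import FrameStack
from .session import AcquisitionError, StagePosition

__all__ = [
    "SpeedProfile",
    "SyntheticRootSpec",
    "SceneWorld",
    "RootWorld",
    "ClusterWorld",
    "make_root_world",
    "make_cluster_world",
    "render_view",
    "SimulatedMicroscope",
]

_FULL_SCALE = 65535  # 16-bit saturation used for salt noise


def _cell_lengths(base_um: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Cell lengths of a root file: short near the tip (meristem), then
    growing ~30%/cell through the elongation zone.  The resulting chirped
    wall pattern has a sharp autocorrelation, as real cell files do."""
    idx = np.arange(n)
    gradient = np.minimum(1.3 ** np.maximum(idx - 10, 0), 4.0)
    return base_um * rng.uniform(0.7, 1.3, size=n) * gradient


def _rot_cw(angle_deg: float) -> np.ndarray:
    """Clockwise-on-screen rotation matrix in (x, y-down) coordinates."""
    t = math.radians(angle_deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s], [s, c]])


def _derive_rng(seed: int, *parts) -> np.random.Generator:
    """Deterministic, platform-stable RNG keyed by the seed and arguments."""
    key = zlib.crc32(repr(parts).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


class SpeedProfile:
    """Piecewise-constant speed (µm/h) over time, e.g. day/night modulation."""

    def __init__(self, segments: Sequence[Tuple[float, float]]):
        segs = sorted((float(t), float(v)) for t, v in segments)
        if not segs or segs[0][0] > 0.0:
            raise ValueError("speed profile must start at t <= 0 h")
        if any(v < 0 for _, v in segs):
            raise ValueError("speeds must be >= 0")
        self.segments = segs

    @classmethod
    def constant(cls, speed: float) -> "SpeedProfile":
        return cls([(0.0, speed)])

    @classmethod
    def day_night(
        cls, day_speed: float, night_speed: float,
        day_h: float = 16.0, night_h: float = 8.0,
        span_h: float = 48.0, start_day: bool = True,
    ) -> "SpeedProfile":
        segs, t, day = [], 0.0, start_day
        while t < span_h:
            segs.append((t, day_speed if day else night_speed))
            t += day_h if day else night_h
            day = not day
        return cls(segs)

    def speed_at(self, t: float) -> float:
        v = self.segments[0][1]
        for start, val in self.segments:
            if t >= start:
                v = val
            else:
                break
        return v

    def distance(self, t: float) -> float:
        """Integral of the speed from 0 to t (arc length grown, µm)."""
        if t <= 0:
            return 0.0
        total = 0.0
        for i, (start, val) in enumerate(self.segments):
            end = self.segments[i + 1][0] if i + 1 < len(self.segments) else math.inf
            lo, hi = max(start, 0.0), min(end, t)
            if hi > lo:
                total += val * (hi - lo)
        return total


@dataclass(frozen=True)
class SyntheticRootSpec:
    """Parameters of the synthetic growing root.

    Defaults describe a vigorous Arabidopsis-like primary root: 150 µm/h
    growth (observed range 50–250, up to 300 µm/h), ~15 µm meristematic
    cells in an ~80 µm-wide tip, division rounds every 12 h (within the
    10–35 h cell-cycle range of transit-amplifying cells), rendered as
    bright cell walls on a dark background.
    """

    start_xy_um: Tuple[float, float] = (0.0, 0.0)
    direction_deg: float = 0.0  # from +y gravity axis, clockwise positive
    speed: Union[float, SpeedProfile] = 150.0
    curvature_deg_per_h: float = 0.0  # gravitropic re-bending toward +y
    cell_length_um: float = 15.0
    n_cells: int = 30
    division_period_h: Optional[float] = 12.0
    root_radius_um: float = 40.0
    wall_halfwidth_um: float = 3.0
    wall_intensity: float = 900.0
    interior_intensity: float = 40.0
    background_intensity: float = 100.0
    noise_sigma: float = 10.0
    salt_pepper_fraction: float = 0.0
    psf_sigma_px: float = 1.0
    defocus_sigma_per_plane_px: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        bad = []
        profile = self.speed if isinstance(self.speed, SpeedProfile) else None
        if profile is None and not self.speed >= 0:
            bad.append("speed")
        if self.cell_length_um <= 0:
            bad.append("cell_length_um")
        if self.n_cells < 1:
            bad.append("n_cells")
        if self.division_period_h is not None and self.division_period_h <= 0:
            bad.append("division_period_h")
        if self.root_radius_um <= 0:
            bad.append("root_radius_um")
        if not (0.0 <= self.salt_pepper_fraction < 0.5):
            bad.append("salt_pepper_fraction")
        if self.noise_sigma < 0:
            bad.append("noise_sigma")
        if self.psf_sigma_px < 0:
            bad.append("psf_sigma_px")
        if bad:
            raise ValueError(f"invalid SyntheticRootSpec field(s): {bad}")

    @property
    def profile(self) -> SpeedProfile:
        if isinstance(self.speed, SpeedProfile):
            return self.speed
        return SpeedProfile.constant(float(self.speed))


class SceneWorld:
    """Base class: a rigid scene transform plus noise/psf parameters.

    ``rotated(centre, angle)`` returns a view of the same world after the
    sample chamber was rotated about ``centre`` (clockwise-positive, same
    convention as position recomputation); model geometry is unchanged,
    only the model→scene transform composes.
    """

    seed: int = 0
    noise_sigma: float = 0.0
    salt_pepper_fraction: float = 0.0
    psf_sigma_px: float = 0.0
    defocus_sigma_per_plane_px: float = 0.7
    background_intensity: float = 100.0

    def __init__(self) -> None:
        self._R = np.eye(2)
        self._T = np.zeros(2)

    def _to_scene(self, pts: np.ndarray) -> np.ndarray:
        return pts @ self._R.T + self._T

    def _to_model_grid(self, xs: np.ndarray, ys: np.ndarray):
        """Map scene-coordinate pixel grids to model coordinates."""
        inv = self._R.T  # rotation: inverse = transpose
        dx, dy = xs - self._T[0], ys - self._T[1]
        return inv[0, 0] * dx + inv[0, 1] * dy, inv[1, 0] * dx + inv[1, 1] * dy

    def rotated(self, centre_xy_um: Tuple[float, float], angle_deg: float) -> "SceneWorld":
        import copy

        rot = _rot_cw(angle_deg)
        c = np.asarray(centre_xy_um, dtype=float)
        out = copy.copy(self)
        out._R = rot @ self._R
        out._T = rot @ self._T + (c - rot @ c)
        return out

    def render_base(
        self,
        time_h: float,
        centre_xy_um: Tuple[float, float],
        frame_px: Tuple[int, int],
        pixel_size: float,
    ) -> np.ndarray:
        """Noise-free, unblurred intensity field of the stage window."""
        h, w = frame_px
        cx, cy = centre_xy_um
        xs = cx + (np.arange(w) - (w - 1) / 2.0) * pixel_size
        ys = cy + (np.arange(h) - (h - 1) / 2.0) * pixel_size
        gx, gy = np.meshgrid(xs, ys)
        mx, my = self._to_model_grid(gx, gy)
        # continuous-domain anti-aliasing: sub-pixel ridges are widened (and
        # proportionally dimmed) to the sampling scale before evaluation
        return self._model_intensity(time_h, mx, my, blur_um=0.6 * pixel_size)

    def _model_intensity(self, time_h, mx, my, blur_um=0.0) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class RootWorld(SceneWorld):
    """Growing root tip with a dividing 1-D cell file.

    The tip advances along the integral of the speed profile; with nonzero
    curvature its instantaneous direction relaxes toward the gravity axis
    (+y) at ``curvature_deg_per_h``.  The root body is rendered as a
    straight tube along the instantaneous direction through the tip; each
    cross-wall sits at a fixed arc length behind the tip, so the wall
    ledger (positions and creation times) is exact ground truth for
    membrane-generation counts.
    """

    _PATH_DT = 0.01  # h; integration step for curved tip paths

    def __init__(self, spec: SyntheticRootSpec):
        spec.validate()
        super().__init__()
        self.spec = spec
        self.seed = spec.seed
        self.noise_sigma = spec.noise_sigma
        self.salt_pepper_fraction = spec.salt_pepper_fraction
        self.psf_sigma_px = spec.psf_sigma_px
        self.defocus_sigma_per_plane_px = spec.defocus_sigma_per_plane_px
        self.background_intensity = spec.background_intensity
        # initial cell file: n_cells cells behind the starting tip (tip arc
        # = 0).  Cell lengths vary ±30% about the nominal value — real cell
        # files are irregular, and the aperiodicity is what gives the
        # correlation surface a unique peak.
        rng = _derive_rng(spec.seed, "cell-file")
        lengths = _cell_lengths(spec.cell_length_um, spec.n_cells, rng)
        arcs = np.concatenate([[0.0], -np.cumsum(lengths)])
        self._walls: List[Tuple[float, float]] = [(float(s), 0.0) for s in arcs]
        self._divided_rounds = 0
        self._path_cache: Optional[Tuple[np.ndarray, np.ndarray]] = None

    # --- kinematics -----------------------------------------------------

    def _direction_at(self, t: float) -> np.ndarray:
        th0 = self.spec.direction_deg
        c = self.spec.curvature_deg_per_h
        th = th0 if c == 0 else math.copysign(max(abs(th0) - c * t, 0.0), th0)
        r = math.radians(th)
        return np.array([math.sin(r), math.cos(r)])

    def _model_tip(self, t: float) -> np.ndarray:
        start = np.asarray(self.spec.start_xy_um, dtype=float)
        prof = self.spec.profile
        if self.spec.curvature_deg_per_h == 0:
            return start + self._direction_at(0.0) * prof.distance(t)
        n = int(math.ceil(t / self._PATH_DT))
        pos = start.copy()
        s_prev = 0.0
        for i in range(n):
            ta, tb = i * self._PATH_DT, min((i + 1) * self._PATH_DT, t)
            ds = prof.distance(tb) - prof.distance(ta)
            pos = pos + self._direction_at((ta + tb) / 2.0) * ds
            s_prev = tb
        return pos

    def tip_position(self, time_h: float) -> Tuple[float, float]:
        """Ground-truth tip position in scene coordinates (µm)."""
        p = self._to_scene(self._model_tip(time_h)[None, :])[0]
        return float(p[0]), float(p[1])

    def arc_length(self, time_h: float) -> float:
        return self.spec.profile.distance(time_h)

    # --- cell file ------------------------------------------------------

    def _ensure_divisions(self, time_h: float) -> None:
        period = self.spec.division_period_h
        if period is None:
            return
        while (self._divided_rounds + 1) * period <= time_h:
            t_div = (self._divided_rounds + 1) * period
            existing = sorted(s for s, _ in self._walls)
            new = [((a + b) / 2.0, t_div) for a, b in zip(existing, existing[1:])]
            self._walls.extend(new)
            self._divided_rounds += 1

    def walls_at(self, time_h: float) -> List[Tuple[float, float]]:
        """Wall ledger: (arc position µm, creation time h) for walls ≤ time."""
        self._ensure_divisions(time_h)
        return [(s, c) for s, c in self._walls if c <= time_h]

    # --- rendering ------------------------------------------------------

    def _model_intensity(self, time_h, mx, my, blur_um=0.0) -> np.ndarray:
        sp = self.spec
        tip = self._model_tip(time_h)
        u = self._direction_at(time_h)
        nvec = np.array([u[1], -u[0]])
        dx, dy = mx - tip[0], my - tip[1]
        s_back = -(dx * u[0] + dy * u[1])  # distance behind the tip, µm
        r = dx * nvec[0] + dy * nvec[1]

        # The rendered root translates rigidly with the tip: every wall sits
        # at a fixed distance behind it (= its arc coordinate negated).  The
        # visible window around the tip therefore moves as one body, which
        # is what the tracker sees on a real root whose meristem advances
        # with the apex; tissue-frame wall bookkeeping stays in arc
        # coordinates for division counting.
        self._ensure_divisions(time_h)
        body_len = -min(s for s, _ in self._walls)
        taper = 2.0 * sp.root_radius_um

        img = np.full(mx.shape, sp.background_intensity, dtype=np.float64)
        in_s = (s_back >= 0) & (s_back <= body_len)
        # hemispherical-ish taper near the tip
        frac = np.clip(s_back / taper, 0.0, 1.0)
        radius = sp.root_radius_um * np.sqrt(np.clip(1.0 - (1.0 - frac) ** 2, 0.0, 1.0))
        inside = in_s & (np.abs(r) < radius)
        img[inside] += sp.interior_intensity

        wh = math.hypot(sp.wall_halfwidth_um, blur_um)
        ridge_gain = sp.wall_halfwidth_um / wh  # integral-conserving dimming
        self._ensure_divisions(time_h)
        wall_ds = np.sort([-s for s, c in self._walls if c <= time_h])

        def paint_file(ds: np.ndarray, sel_band: np.ndarray, key: str) -> None:
            """Cross walls + per-cell cytoplasm of one cell file (a radial
            band of the root), keyed so brightness is stable across renders."""
            cell_idx = np.searchsorted(ds, s_back[sel_band])
            gains = np.array(
                [
                    0.5 + _derive_rng(sp.seed, key, "cell", round(d * 1e6)).uniform()
                    for d in np.concatenate([[0.0], ds])
                ]
            )
            img[sel_band] += sp.interior_intensity * gains[
                np.clip(cell_idx, 0, gains.size - 1)
            ]
            for d_w in ds:
                if d_w < -3 * wh or d_w > body_len + 3 * wh:
                    continue
                g = 0.4 + 0.6 * _derive_rng(sp.seed, key, "wall", round(d_w * 1e6)).uniform()
                sel = sel_band & (np.abs(s_back - d_w) < 4 * wh)
                img[sel] += sp.wall_intensity * ridge_gain * g * np.exp(
                    -0.5 * ((s_back[sel] - d_w) / wh) ** 2
                )

        # three staggered cell files across the radius, like the epidermis /
        # cortex / stele files of a real root: the central file carries the
        # division ledger, the flanking ones are render-only texture
        rel = np.abs(r) / np.maximum(radius, 1e-9)
        central = inside & (rel < 0.4)
        middle = inside & (rel >= 0.4) & (rel < 0.7)
        outer = inside & (rel >= 0.7)
        paint_file(wall_ds, central, "file-central")
        for name, band in (("file-middle", middle), ("file-outer", outer)):
            rng = _derive_rng(sp.seed, name, "layout")
            lengths = _cell_lengths(sp.cell_length_um, max(sp.n_cells, 8), rng)
            ds = np.sort(np.cumsum(lengths) - lengths[0] * rng.uniform())
            paint_file(ds, band, name)
        # root cap / columella: dense small cells make the apex itself the
        # strongest, most distinctive texture — this anchors correlation to
        # the tip rather than the (axially repetitive) cell files behind it
        cap_len = 1.2 * sp.root_radius_um
        in_cap = inside & (s_back < cap_len)
        if np.any(in_cap):
            img[in_cap] += 4.0 * sp.interior_intensity
            tier_rng = _derive_rng(sp.seed, "cap-tiers")
            tiers = np.cumsum(tier_rng.uniform(0.5, 1.1, size=8)) * (cap_len / 6.0)
            for d_t in tiers:
                if d_t >= cap_len:
                    break
                g = 0.5 + 0.5 * _derive_rng(sp.seed, "cap-wall", round(d_t * 1e3)).uniform()
                sel = in_cap & (np.abs(s_back - d_t) < 4 * wh)
                img[sel] += sp.wall_intensity * ridge_gain * g * np.exp(
                    -0.5 * ((s_back[sel] - d_t) / wh) ** 2
                )
        # side walls: dimmer ridge at the tube boundary
        edge = in_s & (radius > 0)
        edge_d = np.abs(np.abs(r) - radius)
        img[edge] += 0.5 * sp.wall_intensity * ridge_gain * np.exp(
            -0.5 * (edge_d[edge] / wh) ** 2
        )
        return img


class ClusterWorld(SceneWorld):
    """Migrating cluster of overlapping soft-disk cells.

    ``centroid_path`` maps time (h) to the cluster centroid (µm); cell
    offsets are drawn once from the seed (and recentred so the rendered
    centroid matches the path), with a small deterministic sinusoidal
    jitter per cell emulating cell motility within the cluster.
    """

    def __init__(
        self,
        centroid_path: Callable[[float], Tuple[float, float]],
        n_cells: int = 20,
        cell_radius_um: float = 10.0,
        cluster_radius_um: float = 30.0,
        jitter_um: float = 1.5,
        cell_intensity: float = 600.0,
        background_intensity: float = 100.0,
        noise_sigma: float = 10.0,
        salt_pepper_fraction: float = 0.0,
        psf_sigma_px: float = 1.0,
        seed: int = 0,
    ):
        if n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        super().__init__()
        self.path = centroid_path
        self.n_cells = n_cells
        self.cell_radius_um = cell_radius_um
        self.cell_intensity = cell_intensity
        self.jitter_um = jitter_um
        self.seed = seed
        self.noise_sigma = noise_sigma
        self.salt_pepper_fraction = salt_pepper_fraction
        self.psf_sigma_px = psf_sigma_px
        self.background_intensity = background_intensity
        rng = _derive_rng(seed, "cluster-offsets")
        off = rng.normal(0.0, cluster_radius_um / 2.0, size=(n_cells, 2))
        self._offsets = off - off.mean(axis=0)
        self._phases = rng.uniform(0.0, 2 * math.pi, size=(n_cells, 2))
        self._freqs = rng.uniform(0.3, 1.0, size=(n_cells, 2))  # cycles/h

    def centroid_true(self, time_h: float) -> Tuple[float, float]:
        p = np.asarray(self.path(time_h), dtype=float)
        return tuple(self._to_scene(p[None, :])[0])

    def _model_intensity(self, time_h, mx, my, blur_um=0.0) -> np.ndarray:
        cx, cy = self.path(time_h)
        jit = self.jitter_um * np.sin(
            2 * math.pi * self._freqs * time_h + self._phases
        )
        centres = np.asarray([cx, cy]) + self._offsets + jit
        img = np.full(mx.shape, self.background_intensity, dtype=np.float64)
        edge = max(self.cell_radius_um * 0.15, 0.5)
        for px, py in centres:
            d = np.hypot(mx - px, my - py)
            img += self.cell_intensity / (1.0 + np.exp((d - self.cell_radius_um) / edge))
        return img


def make_root_world(spec: SyntheticRootSpec) -> RootWorld:
    """Build a growing-root world; raises listing any invalid spec fields."""
    return RootWorld(spec)


def make_cluster_world(
    centroid_path: Callable[[float], Tuple[float, float]],
    n_cells: int = 20,
    cell_radius_um: float = 10.0,
    noise: Tuple[float, float] = (10.0, 0.0),
    seed: int = 0,
    **kwargs,
) -> ClusterWorld:
    """Build a migrating-cluster world; ``noise`` = (gaussian σ, s&p fraction)."""
    return ClusterWorld(
        centroid_path,
        n_cells=n_cells,
        cell_radius_um=cell_radius_um,
        noise_sigma=noise[0],
        salt_pepper_fraction=noise[1],
        seed=seed,
        **kwargs,
    )


def render_view(
    world: SceneWorld,
    stage: StagePosition,
    frame_px: Tuple[int, int],
    pixel_size: float,
    n_z: int,
    time_h: float,
    time_index: int = 0,
) -> FrameStack:
    """Render the world window centred at a stage position as a z-stack.

    Plane i is blurred with σ = psf_sigma_px + i·defocus_sigma_per_plane_px
    (progressive defocus away from the focal plane); Gaussian and
    salt-and-pepper noise are then applied per plane.  Deterministic given
    the world seed and all arguments.
    """
    if n_z < 1:
        raise ValueError("n_z must be >= 1")
    base = world.render_base(time_h, (stage.x_um, stage.y_um), frame_px, pixel_size)
    planes = []
    for i in range(n_z):
        sigma = world.psf_sigma_px + i * world.defocus_sigma_per_plane_px
        plane = ndimage.gaussian_filter(base, sigma) if sigma > 0 else base.copy()
        rng = _derive_rng(
            world.seed,
            "render", round(time_h * 1e6), round(stage.x_um * 1e3),
            round(stage.y_um * 1e3), frame_px, pixel_size, n_z, i,
        )
        if world.noise_sigma > 0:
            plane = plane + rng.normal(0.0, world.noise_sigma, size=plane.shape)
        if world.salt_pepper_fraction > 0:
            # impulses at the image's own dynamic range (dead / saturated
            # pixels of the signal actually present, not the ADC full scale)
            n_px = plane.size
            n_sp = int(round(world.salt_pepper_fraction * n_px))
            idx = rng.choice(n_px, size=n_sp, replace=False)
            flat = plane.reshape(-1)
            half = n_sp // 2
            salt = float(plane.max())
            flat[idx[:half]] = 0.0
            flat[idx[half:]] = salt
        planes.append(np.clip(plane, 0, _FULL_SCALE))
    stack = np.rint(np.stack(planes)).astype(np.uint16)[None, :, :, :]
    return FrameStack(
        intensities=stack,
        pixel_size=pixel_size,
        time_index=time_index,
        time_h=time_h,
        specimen_id=stage.specimen_id,
    )


class SimulatedMicroscope:
    """Stand-in for the stage/scanhead satisfying the microscope contract.

    Acquires one stack per active specimen at the last loaded position
    list, with optional Gaussian stage repositioning error.
    """

    def __init__(
        self,
        worlds: Dict[str, SceneWorld],
        frame_px: Tuple[int, int] = (1400, 1400),
        pixel_size: float = 0.457,
        n_z: int = 14,
        stage_error_sigma_um: float = 0.0,
        seed: int = 0,
    ):
        self.worlds = dict(worlds)
        self._frame_px = tuple(frame_px)
        self._pixel_size = float(pixel_size)
        self.n_z = int(n_z)
        self.stage_error_sigma_um = float(stage_error_sigma_um)
        self.seed = int(seed)
        self._positions: List[StagePosition] = []

    @property
    def pixel_size(self) -> float:
        return self._pixel_size

    @property
    def frame_shape(self) -> Tuple[int, int]:
        return self._frame_px

    def load_position_list(self, positions: Sequence[StagePosition]) -> None:
        for p in positions:
            if p.specimen_id not in self.worlds:
                raise KeyError(f"unknown specimen_id '{p.specimen_id}'")
        self._positions = list(positions)

    def acquire(self, time_index: int, time_h: float) -> Dict[str, FrameStack]:
        if not self._positions:
            raise AcquisitionError("no position list loaded")
        out: Dict[str, FrameStack] = {}
        for i, pos in enumerate(self._positions):
            if not pos.active:
                continue
            actual = pos
            if self.stage_error_sigma_um > 0:
                rng = _derive_rng(self.seed, "stage", time_index, i)
                jx, jy = rng.normal(0.0, self.stage_error_sigma_um, size=2)
                actual = replace(pos, x_um=pos.x_um + jx, y_um=pos.y_um + jy)
            out[pos.specimen_id] = render_view(
                self.worlds[pos.specimen_id],
                actual,
                self._frame_px,
                self._pixel_size,
                self.n_z,
                time_h,
                time_index=time_index,
            )
        return out
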