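"""Config-file parsing: tracker settings and synthetic-scene specifications.

Both files are flat key–value YAML.  A scene file describes the simulated
specimens and stage; a tracker file overrides :class:`TrackerConfig`
defaults.  Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Tuple

import yaml

from .core import AxisMap, TrackerConfig
from .scene import (
    ClusterWorld,
    RootWorld,
    SceneWorld,
    SpeedProfile,
    SyntheticRootSpec,
)
from .session import StagePosition

__all__ = ["load_tracker_config", "load_scene", "tracker_config_to_dict"]

_TRACKER_KEYS = {
    "roi_fraction",
    "mean_kernel_px",
    "median_kernel_px",
    "max_step_um",
    "tracking_channel",
    "subpixel",
    "axis_sign_x",
    "axis_sign_y",
    "axis_swap_xy",
}


def load_tracker_config(path) -> TrackerConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _TRACKER_KEYS
    if unknown:
        raise ValueError(f"unknown tracker config key(s): {sorted(unknown)}")
    axis = AxisMap(
        sign_x=int(raw.pop("axis_sign_x", 1)),
        sign_y=int(raw.pop("axis_sign_y", 1)),
        swap_xy=bool(raw.pop("axis_swap_xy", False)),
    )
    return TrackerConfig(axis_map=axis, **raw)


def tracker_config_to_dict(cfg: TrackerConfig) -> dict:
    return {
        "roi_fraction": cfg.roi_fraction,
        "mean_kernel_px": cfg.mean_kernel_px,
        "median_kernel_px": cfg.median_kernel_px,
        "max_step_um": cfg.max_step_um,
        "tracking_channel": cfg.tracking_channel,
        "subpixel": cfg.subpixel,
        "axis_sign_x": cfg.axis_map.sign_x,
        "axis_sign_y": cfg.axis_map.sign_y,
        "axis_swap_xy": cfg.axis_map.swap_xy,
    }


def _build_root(entry: dict, seed: int) -> RootWorld:
    if "speed_profile" in entry:
        speed = SpeedProfile([(float(t), float(v)) for t, v in entry["speed_profile"]])
    else:
        speed = float(entry.get("speed_um_per_h", 150.0))
    spec = SyntheticRootSpec(
        start_xy_um=(float(entry.get("start_x_um", 0.0)), float(entry.get("start_y_um", 0.0))),
        direction_deg=float(entry.get("direction_deg", 0.0)),
        speed=speed,
        curvature_deg_per_h=float(entry.get("curvature_deg_per_h", 0.0)),
        cell_length_um=float(entry.get("cell_length_um", 15.0)),
        n_cells=int(entry.get("n_cells", 30)),
        division_period_h=entry.get("division_period_h", 12.0),
        root_radius_um=float(entry.get("root_radius_um", 40.0)),
        noise_sigma=float(entry.get("noise_sigma", 10.0)),
        salt_pepper_fraction=float(entry.get("salt_pepper_fraction", 0.0)),
        psf_sigma_px=float(entry.get("psf_sigma_px", 1.0)),
        seed=seed,
    )
    return RootWorld(spec)


def _build_cluster(entry: dict, seed: int) -> ClusterWorld:
    x0 = float(entry.get("start_x_um", 0.0))
    y0 = float(entry.get("start_y_um", 0.0))
    vx = float(entry.get("velocity_x_um_per_h", 0.0))
    vy = float(entry.get("velocity_y_um_per_h", 0.0))
    return ClusterWorld(
        centroid_path=lambda t: (x0 + vx * t, y0 + vy * t),
        n_cells=int(entry.get("n_cells", 20)),
        cell_radius_um=float(entry.get("cell_radius_um", 10.0)),
        noise_sigma=float(entry.get("noise_sigma", 10.0)),
        salt_pepper_fraction=float(entry.get("salt_pepper_fraction", 0.0)),
        seed=seed,
    )


def load_scene(path, seed: int = 0) -> Tuple[Dict[str, SceneWorld], dict, List[StagePosition]]:
    """Parse a scene file.

    Returns (worlds by specimen id, simulated-microscope keyword arguments,
    initial stage positions centred on each specimen's start point).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    specimens = raw.get("specimens")
    if not specimens:
        raise ValueError(f"{path}: scene file lists no specimens")
    worlds: Dict[str, SceneWorld] = {}
    positions: List[StagePosition] = []
    for i, entry in enumerate(specimens):
        sid = str(entry.get("id", f"specimen{i}"))
        if sid in worlds:
            raise ValueError(f"{path}: duplicate specimen id '{sid}'")
        kind = entry.get("kind", "root")
        wseed = (seed * 10007 + i * 101) % (2**31)
        if kind == "root":
            worlds[sid] = _build_root(entry, wseed)
        elif kind == "cluster":
            worlds[sid] = _build_cluster(entry, wseed)
        else:
            raise ValueError(f"{path}: unknown specimen kind '{kind}'")
        positions.append(
            StagePosition(
                sid,
                float(entry.get("start_x_um", 0.0)),
                float(entry.get("start_y_um", 0.0)),
            )
        )
    fp = raw.get("frame_px", 1400)
    frame_px = tuple(fp) if isinstance(fp, (list, tuple)) else (int(fp), int(fp))
    micro_kwargs = {
        "frame_px": frame_px,
        "pixel_size": float(raw.get("pixel_size_um", 0.457)),
        "n_z": int(raw.get("n_z", 14)),
        "stage_error_sigma_um": float(raw.get("stage_error_sigma_um", 0.0)),
        "seed": seed % (2**31),
    }
    return worlds, micro_kwargs, positions
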