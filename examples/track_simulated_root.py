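"""Track a synthetic growing root closed-loop and print its trajectory.

A root world growing at 150 µm/h is imaged every 20 min by the simulated
microscope (640 µm field of view sampled at 2 µm/px).  The session
estimates the shift at each time point, predicts the next stage position,
and the printed table shows the loop converging: after the uncompensated
first interval the stage advances ~50 µm per step and the residual shift
drops to zero.
"""

import numpy as np

from apextrack import (
    SimulatedMicroscope,
    StagePosition,
    SyntheticRootSpec,
    TrackerConfig,
    make_root_world,
    run_session,
)

world = make_root_world(SyntheticRootSpec(speed=150.0, noise_sigma=10.0, seed=3))
microscope = SimulatedMicroscope(
    {"root1": world}, frame_px=(320, 320), pixel_size=2.0, n_z=3,
    stage_error_sigma_um=0.5, seed=7,
)
log = run_session(
    microscope,
    [StagePosition("root1", 0.0, 0.0)],
    TrackerConfig(max_step_um=200.0),
    n_timepoints=8,
    interval_h=1 / 3,
)

print(f"{'t':>3} {'stage y (um)':>13} {'shift dy (px)':>14} {'tip offset (um)':>16}")
for rec in log.for_specimen("root1"):
    tx, ty = world.tip_position(rec.time_h)
    offset = np.hypot(tx - rec.x_um, ty - rec.y_um)
    dy = "-" if rec.dy_px is None else f"{rec.dy_px:+.0f}"
    print(f"{rec.time_index:>3} {rec.y_um:>13.1f} {dy:>14} {offset:>16.1f}")
print(
    "\nThe stage follows the root at its growth rate (50 um per 20-min step);"
    "\nthe constant tip offset is the uncompensated first interval."
)
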