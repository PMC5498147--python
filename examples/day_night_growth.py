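"""Recover day/night growth kinetics from a closed-loop tracking session.

The synthetic root grows at 250 µm/h with the light on and 50 µm/h in the
dark, mimicking the diurnal modulation seen in long-term root imaging.  The
session tracks it for 24 h at 20-min intervals; growth rates derived from
the recorded positions are annotated with the light schedule and the
per-phase medians are printed — they recover the programmed speeds.
"""

import numpy as np

from apextrack import (
    LightSchedule,
    SimulatedMicroscope,
    SpeedProfile,
    StagePosition,
    SyntheticRootSpec,
    TrackerConfig,
    annotate_light,
    growth_rates,
    make_root_world,
    run_session,
)
from apextrack.kinetics import LightInterval

profile = SpeedProfile([(0.0, 250.0), (12.0, 50.0)])  # day then night
world = make_root_world(SyntheticRootSpec(speed=profile, noise_sigma=10.0, seed=42))
microscope = SimulatedMicroscope(
    {"r": world}, frame_px=(320, 320), pixel_size=2.0, n_z=3,
    stage_error_sigma_um=1.0, seed=42,
)
log = run_session(
    microscope, [StagePosition("r", 0.0, 0.0)],
    TrackerConfig(max_step_um=200.0), n_timepoints=73, interval_h=1 / 3,
)

schedule = LightSchedule([
    LightInterval(0.0, 12.0, True), LightInterval(12.0, 24.5, False),
])
series = annotate_light(growth_rates(log), schedule)
day = np.median([p.rate_um_per_h for p in series.rates["r"] if p.light_on])
night = np.median([p.rate_um_per_h for p in series.rates["r"] if not p.light_on])
print(f"programmed day rate:   250 um/h   recovered: {day:6.1f} um/h")
print(f"programmed night rate:  50 um/h   recovered: {night:6.1f} um/h")
print("\nPer-phase medians of the per-interval rates; the ~2 um/h excess is")
print("pixel quantization of the integer-shift estimate.")
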