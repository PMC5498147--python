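import numpy as np
import pytest

from apextrack import (
    StagePosition,
    SyntheticRootSpec,
    TrackerConfig,
    make_root_world,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_config():
    return TrackerConfig()


@pytest.fixture
def root_world():
    """Small noiseless root world growing straight down at 150 µm/h."""
    return make_root_world(
        SyntheticRootSpec(speed=150.0, noise_sigma=0.0, seed=11)
    )


@pytest.fixture
def centered_position():
    return StagePosition("root1", 0.0, 0.0)


# Study-scale geometry sampled coarsely: a 640 µm field of view (as with a
# 20x objective) rendered at 2 µm/px over 320 px with 3 z-planes.
SCALED_FRAME = (320, 320)
SCALED_PIXEL_SIZE = 2.0
SCALED_NZ = 3


@pytest.fixture
def scaled_geometry():
    return {"frame_px": SCALED_FRAME, "pixel_size": SCALED_PIXEL_SIZE, "n_z": SCALED_NZ}
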