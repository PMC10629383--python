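import numpy as np
import pytest

from skystrip.config import SurveyConfig
from skystrip.geometry import CameraModel, Pose


@pytest.fixture
def config():
    return SurveyConfig()


@pytest.fixture
def camera():
    return CameraModel(
        focal_length=0.050,
        sensor_width=0.0232,
        sensor_height=0.0154,
        pixels=(6016, 4000),
        mount_tilt=0.0,
    )


@pytest.fixture
def tilted_camera():
    return CameraModel(
        focal_length=0.050,
        sensor_width=0.0232,
        sensor_height=0.0154,
        pixels=(6016, 4000),
        mount_tilt=11.5,
    )


@pytest.fixture
def nadir_pose():
    return Pose(0.0, 0.0, 396.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
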