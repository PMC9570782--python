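import numpy as np
import pytest

from fishmetrics import CameraIntrinsics, SimConfig, SonarGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def intrinsics():
    return CameraIntrinsics(f=1000.0, cx=960.0, cy=540.0, baseline=11.0)


@pytest.fixture
def pond_geometry():
    """Geometry of the reference 630 x 600 cm pond at 1080 x 1092 pixels."""
    return SonarGeometry(
        pixel_width=630.0 / 1080.0,
        pixel_height=600.0 / 1092.0,
        device_position=(630.0, 0.0, 0.0),
        image_shape=(1080, 1092),
    )


@pytest.fixture
def sim_config():
    return SimConfig(seed=42)


@pytest.fixture
def small_sim_config():
    """Scaled-down study conditions for fast mask/sequence fixtures."""
    return SimConfig(seed=42, n_fish=60, table_rows=50, n_frames=12)
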