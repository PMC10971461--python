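import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ofrlab import synthetic, tracking

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_camera() -> synthetic.CameraModel:
    """A miniature camera geometry so rendered-frame tests stay fast."""
    return synthetic.CameraModel(
        frame_width_px=320,
        frame_height_px=240,
        pupil_radius_px=18.0,
        iris_radius_px=42.0,
        marker_radius_px=7.0,
        pupil_center=(220.0, 120.0),
        marker_center=(70.0, 120.0),
        px_per_deg=40.0,
    )


@pytest.fixture(scope="session")
def detection_configs(small_camera):
    return tracking.detection_configs_for(small_camera)


@pytest.fixture(scope="session")
def marker_exclusion(small_camera) -> float:
    return small_camera.iris_radius_px * 1.5
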