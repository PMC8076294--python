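import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fundusphere.geometry import EyeModel, FundusFrame

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def eye24() -> EyeModel:
    """The 24-mm schematic eye (radius 12 mm)."""
    return EyeModel(24.0)


@pytest.fixture
def frame1000() -> FundusFrame:
    """A 1000x1000 frame with the default 200-degree field."""
    return FundusFrame(1000, 1000)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)


def random_infield_pixels(rng, frame, n, margin=0.0):
    """Uniform pixels inside the calibrated image circle."""
    ang = rng.uniform(0.0, 2.0 * np.pi, n)
    r = frame.radius_px * (1.0 - margin) * np.sqrt(rng.uniform(0.0, 1.0, n))
    cx, cy = frame.center_px
    return np.stack([cx + r * np.cos(ang), cy + r * np.sin(ang)], axis=-1)


def random_sphere_points(rng, n, max_colat_deg=179.0):
    """Uniform directions on the cap within max_colat_deg of the posterior pole."""
    z_lo = -np.cos(np.radians(max_colat_deg))
    z = rng.uniform(-1.0, z_lo, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    s = np.sqrt(1.0 - z**2)
    return np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=-1)
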