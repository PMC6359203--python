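import numpy as np
import pytest

from phytocloud import ColoredPointCloud
from phytocloud.chlorophyll import CalibrationCurve
from phytocloud.cloud import CALIBRATED


@pytest.fixture
def rng():
    return np.random.default_rng(20240131)


@pytest.fixture
def design_curve():
    return CalibrationCurve(slope=-40.0, intercept=22.0, r_squared=1.0, n=0)


@pytest.fixture
def random_calibrated_cloud(rng):
    """Unstructured colored cloud in the calibrated frame."""
    n = 500
    return ColoredPointCloud(
        points=rng.uniform(-5, 5, (n, 3)),
        colors=rng.integers(1, 255, (n, 3)),
        frame=CALIBRATED,
    )


def planar_patch(zenith_deg, azimuth_deg, n=800, extent=1.5, noise=0.0,
                 seed=0, center=(0.0, 0.0, 10.0)):
    """Disk-shaped planar patch with normal at (zenith, azimuth)."""
    rng = np.random.default_rng(seed)
    t, p = np.radians(zenith_deg), np.radians(azimuth_deg)
    normal = np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])
    helper = np.array([1.0, 0.0, 0.0]) if abs(normal[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    radius = extent * np.sqrt(rng.uniform(0, 1, n))
    angle = rng.uniform(0, 2 * np.pi, n)
    uv = np.column_stack([radius * np.cos(angle), radius * np.sin(angle)])
    points = (uv[:, :1] * e1 + uv[:, 1:] * e2
              + np.asarray(center, dtype=np.float64))
    if noise > 0:
        points = points + rng.normal(0, noise, (n, 1)) * normal
    colors = np.full((n, 3), [80, 140, 90], dtype=np.uint8)
    cloud = ColoredPointCloud(points=points, colors=colors, frame=CALIBRATED)
    return cloud, normal
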