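import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from dropstress import PipelineConfig, segment_droplet
from dropstress import phantoms as ph
from dropstress.pipeline import contour_to_profile


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def disc_param():
    return ph.ParametricContour(R0=6.5)


@pytest.fixture(scope="session")
def pear_param():
    # flattened flank centred at +/- pi/2; centroid stays at the origin
    return ph.ParametricContour(R0=6.5, a2=0.10)


@pytest.fixture(scope="session")
def disc_segmented(disc_param):
    """Rendered and segmented resting disc at 0.1 um pixels."""
    c = ph.make_parametric_contour(disc_param)
    img = ph.render_contour_image(c, 0.1, seed=11)
    return c, img, segment_droplet(img)


@pytest.fixture(scope="session")
def pear_segmented(pear_param):
    """Rendered and segmented deformed (pear) droplet at 0.1 um pixels."""
    c = ph.make_parametric_contour(pear_param)
    img = ph.render_contour_image(c, 0.1, seed=12)
    return c, img, segment_droplet(img)


@pytest.fixture(scope="session")
def disc_profile(disc_segmented, config):
    return contour_to_profile(disc_segmented[2], config)


@pytest.fixture(scope="session")
def pear_profile(pear_segmented, config):
    return contour_to_profile(pear_segmented[2], config)


def finite_difference_curvature(points: np.ndarray) -> np.ndarray:
    """Independent curvature oracle: central differences on a closed polygon."""
    x, y = points[:, 0], points[:, 1]
    xp = (np.roll(x, -1) - np.roll(x, 1)) / 2.0
    yp = (np.roll(y, -1) - np.roll(y, 1)) / 2.0
    xpp = np.roll(x, -1) - 2 * x + np.roll(x, 1)
    ypp = np.roll(y, -1) - 2 * y + np.roll(y, 1)
    return (xp * ypp - yp * xpp) / (xp**2 + yp**2) ** 1.5


def turning_number(points: np.ndarray) -> float:
    """Integral of kappa ds / (2 pi) via exterior angles of the polygon."""
    d = np.diff(np.vstack([points, points[:1]]), axis=0)
    ang = np.arctan2(d[:, 1], d[:, 0])
    ext = np.diff(np.concatenate([ang, ang[:1]]))
    ext = np.mod(ext + np.pi, 2 * np.pi) - np.pi
    return float(ext.sum() / (2 * np.pi))
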