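import math

import numpy as np
import pytest

from spindleshape import Contour2D, ModelParams


def make_ellipse(
    a: float,
    b: float,
    angle_deg: float = 0.0,
    center=(0.0, 0.0),
    n: int = 192,
) -> Contour2D:
    """Polygonal ellipse with semi-axes a, b rotated by angle_deg."""
    t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    pts = np.column_stack((a * np.cos(t), b * np.sin(t)))
    rad = math.radians(angle_deg)
    rot = np.array([[math.cos(rad), -math.sin(rad)], [math.sin(rad), math.cos(rad)]])
    return Contour2D(pts @ rot.T + np.asarray(center, dtype=float))


@pytest.fixture
def unit_square() -> Contour2D:
    return Contour2D(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]))


@pytest.fixture
def circle_64() -> Contour2D:
    return make_ellipse(10.0, 10.0, n=64)


@pytest.fixture
def fast_params() -> ModelParams:
    """Cheap but representative model parameters for unit tests."""
    return ModelParams(
        spindle_length_mode="fraction", center_mode="centroid", n_rays=90, dtheta=2.0
    )
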