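import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from glenvault import LandmarkSet


@pytest.fixture
def rng():
    return np.random.default_rng(20250929)


def random_rigid(rng):
    """A uniform random rotation matrix and a translation in ±200 mm."""
    q = rng.normal(size=4)
    R = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
    t = rng.uniform(-200.0, 200.0, size=3)
    return R, t


BASE_POINTS = {
    "inferior_angle": [-70.0, 0.0, -80.0],
    "glenoid_center": [0.0, 0.0, 0.0],
    "medial_point": [-100.0, 0.0, 0.0],
    "medial_border_tip": [-99.0, 12.0, 0.0],
    "vault_tip": [-30.0, 0.0, 0.0],
    "anterior_rim": [2.0, 14.0, 0.0],
    "posterior_rim": [-2.0, -14.0, 0.0],
}


def make_landmarks(shoulder_id="T0", side="right", dominance="unknown", **overrides):
    """A geometrically valid shoulder with selected landmarks overridden."""
    pts = {k: list(v) for k, v in BASE_POINTS.items()}
    pts.update(overrides)
    return LandmarkSet(shoulder_id=shoulder_id, side=side, dominance=dominance, points=pts)
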