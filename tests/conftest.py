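import numpy as np
import pytest

from toothmotion import PointCloud, RigidTransform


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def random_rigid(rng, max_angle_deg=180.0, max_trans_mm=10.0):
    """Random proper rigid transform (uniform axis, uniform angle)."""
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, max_angle_deg)
    A = RigidTransform.from_axis_angle(axis, angle).A
    o = rng.uniform(-max_trans_mm, max_trans_mm, 3)
    return RigidTransform(A, o)


def random_cloud(rng, n=20, scale=10.0, labels=None):
    return PointCloud(rng.uniform(-scale, scale, (n, 3)), labels)
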