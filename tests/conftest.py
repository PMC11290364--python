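import numpy as np
import pytest

from chewkin.geometry import MarkerConstellation, RigidTransform


def random_rotation(rng, max_angle_deg=180.0):
    """Uniform-axis rotation with angle up to max_angle_deg."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(-max_angle_deg, max_angle_deg))
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def random_transform(rng, max_angle_deg=180.0, max_translation=10.0):
    return RigidTransform(
        random_rotation(rng, max_angle_deg),
        rng.uniform(-max_translation, max_translation, size=3),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tetra_constellation():
    """A well-spread 4-marker reference constellation (mm)."""
    coords = np.array(
        [
            [2.0, 0.5, 0.8],
            [-1.5, 1.2, -1.0],
            [0.3, -1.4, 1.6],
            [-0.8, -0.3, -1.4],
        ]
    )
    return MarkerConstellation("bone", ("m1", "m2", "m3", "m4"), coords)
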