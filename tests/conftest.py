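import numpy as np
import pytest

from gaitmood.joints import JOINTS_25
from gaitmood.skeleton_io import GaitRecord


def make_record(xyz, subject="S01", condition="neutral", camera="K1", frame_rate=30.0):
    return GaitRecord(
        subject_id=subject,
        condition=condition,
        camera_id=camera,
        xyz=np.asarray(xyz, dtype=float),
        frame_rate=frame_rate,
    )


def random_record(rng, n_frames=10):
    """A structurally valid record with arbitrary finite coordinates."""
    return make_record(rng.normal(0, 1, size=(n_frames, 25, 3)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_record(rng):
    return random_record(rng, n_frames=10)


@pytest.fixture
def straight_walk_record():
    """Noise-free walk straight toward the camera: z decreasing, y bobbing."""
    n = 120
    t = np.arange(n) / 30.0
    xyz = np.zeros((n, 25, 3))
    for j, joint in enumerate(JOINTS_25):
        xyz[:, j, 0] = 0.01 * j
        xyz[:, j, 1] = 1.0 + 0.02 * j + 0.01 * np.sin(2 * np.pi * 1.0 * t)
        xyz[:, j, 2] = 6.0 - 1.2 * t + 0.05 * np.sin(2 * np.pi * 1.0 * t + j)
    return make_record(xyz)
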