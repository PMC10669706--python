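import numpy as np
import pytest

from posturekit.cop import COPTrajectory, OriginRef
from posturekit.io import default_geometry


@pytest.fixture
def geometry():
    """500 x 500 mm plate, sensors on the corners."""
    return default_geometry()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_traj(xy, fs=100.0, centered=True):
    """Build a trajectory marked centered (metrics-ready) or raw."""
    method = "mean" if centered else "plate_origin"
    return COPTrajectory(
        xy=np.asarray(xy, dtype=float),
        sampling_rate=fs,
        origin_reference=OriginRef((0.0, 0.0), method),
    )


def random_walk(rng, n=500, step_mm=1.0, fs=100.0):
    """Centered bounded random-walk trajectory for property tests."""
    steps = rng.normal(scale=step_mm, size=(n, 2))
    xy = np.cumsum(steps, axis=0)
    xy -= xy.mean(axis=0)
    return make_traj(xy, fs=fs, centered=True)
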