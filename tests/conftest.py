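import numpy as np
import pytest

from mapdyn.spatial import SpatialTransform, rotation_about_axis
from mapdyn.synthetic import (TrajectorySpec, default_channels,
                              generate_measurements, make_biped_model,
                              make_chain_model, simulate_trajectory)


def random_rotation(rng):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    return rotation_about_axis(axis, rng.uniform(-np.pi, np.pi))


def random_transform(rng):
    return SpatialTransform(random_rotation(rng), rng.normal(size=3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def biped():
    return make_biped_model()


@pytest.fixture(scope="session")
def chain5():
    return make_chain_model(5, seed=42)


@pytest.fixture(scope="session")
def gait_gt(biped):
    """Short walking-like ground-truth trial on the 5-link biped."""
    spec = TrajectorySpec(biped,
                          schedule=[("double", 0.2), ("right", 0.5),
                                    ("double", 0.2), ("left", 0.5),
                                    ("double", 0.2)],
                          rate=50.0, seed=7)
    return simulate_trajectory(spec)


@pytest.fixture(scope="session")
def gait_channels(biped):
    return default_channels(biped, ["RF", "LF"])


@pytest.fixture(scope="session")
def gait_measurements(gait_gt, gait_channels):
    return generate_measurements(gait_gt, gait_channels, noise_std=0.0)
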