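import numpy as np
import pytest

from morphobarcode import LandmarkConfiguration, LandmarkDataset
from morphobarcode.simulate import WING_TEMPLATE


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def wing():
    """Unit-size, centred copy of the wing template."""
    c = WING_TEMPLATE - WING_TEMPLATE.mean(axis=0)
    return c / np.sqrt(np.sum(c**2))


def make_dataset(coords_list, labels=None, replicates=None):
    labels = labels or [f"sp" for _ in coords_list]
    replicates = replicates or [0] * len(coords_list)
    configs = [
        LandmarkConfiguration(f"s{i:03d}", lab, c, replicate_index=rep)
        for i, (c, lab, rep) in enumerate(zip(coords_list, labels, replicates))
    ]
    return LandmarkDataset.from_configurations(configs)


@pytest.fixture
def random_wing_dataset(rng, wing):
    """20 noisy wings under random similarity transforms."""
    coords = []
    for _ in range(20):
        shape = wing + rng.normal(0, 0.005, size=wing.shape)
        theta = rng.uniform(0, 2 * np.pi)
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        coords.append(shape @ R.T * rng.uniform(0.5, 2.0) + rng.uniform(-5, 5, 2))
    return make_dataset(coords)
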