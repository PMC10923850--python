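import numpy as np
import pytest

from treestrat import (
    BinaryDataset,
    FitConfig,
    TreeTopology,
    fit,
    make_simple_case,
    sample_dataset,
)


@pytest.fixture(scope="session")
def simple_topology():
    """The 7-feature, 3-module reference wiring (sizes [3, 2, 2])."""
    return TreeTopology.from_sizes([3, 2, 2])


@pytest.fixture(scope="session")
def simple_truth():
    return make_simple_case(seed=3)


@pytest.fixture(scope="session")
def exhaustive_dataset(simple_truth):
    return sample_dataset(simple_truth, mode="exhaustive")


@pytest.fixture(scope="session")
def fitted_model(exhaustive_dataset, simple_truth):
    return fit(exhaustive_dataset, simple_truth.topology, FitConfig(seed=11))


def random_dataset(topology, s, seed, label_prob=0.5):
    """Unstructured random binary dataset matching a topology."""
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 2, size=(s, topology.n_features), dtype=np.int8)
    y = (rng.random(s) < label_prob).astype(np.int8)
    return BinaryDataset(X, y, topology.feature_names)
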