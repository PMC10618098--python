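import numpy as np
import pytest

from brainctl import (CohortConfig, StructuralNetwork, generate_connectome,
                      normalize_dynamics)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_network():
    """Deterministic 12-node weighted connectome."""
    return generate_connectome(12, density=0.4, seed=42)


@pytest.fixture
def small_dynamics(small_network):
    return normalize_dynamics(small_network)


@pytest.fixture
def tiny_cohort_config():
    """Fast cohort: 4+4 subjects on 20 nodes."""
    return CohortConfig(n_controls=4, n_relatives=4, n_nodes=20, seed=7)


def random_network(n, rng, density=0.5):
    """Ad-hoc valid StructuralNetwork with uniform weights."""
    W = np.where(rng.uniform(size=(n, n)) < density,
                 rng.uniform(0.1, 2.0, size=(n, n)), 0.0)
    W = np.triu(W, 1)
    W = W + W.T
    return StructuralNetwork(tuple(f"n{i}" for i in range(n)), W)
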