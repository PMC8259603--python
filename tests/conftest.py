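import numpy as np
import pytest

from sparsegs import (SimulationConfig, compute_grm, filter_markers,
                      simulate_dataset)


@pytest.fixture(scope="session")
def small_dataset():
    """6 families x 20 DH lines, 3 environments — shared across tests."""
    cfg = SimulationConfig(n_families=6, family_size=20, n_chromosomes=4,
                           markers_per_chromosome=50, seed=42)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_grm(small_dataset):
    return compute_grm(filter_markers(small_dataset.marker_matrix, 0.05))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
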