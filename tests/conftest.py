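import numpy as np
import pytest

from poolcomp.synthetic import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_accessions=3, n_markers=400, seed=123)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """Five accessions at a desk-scale marker count (shared, read-only)."""
    return simulate_dataset(SimConfig(n_markers=800, seed=2024))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(99)
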