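import numpy as np
import pytest

from tetradiv.simulate import SimulationConfig, simulate_tetraploid


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete simulated dataset shared across tests."""
    cfg = SimulationConfig(
        seed=11,
        n_chromosomes=2,
        chrom_length=100_000,
        n_genes_per_chrom=20,
        te_fraction=0.1,
    )
    return simulate_tetraploid(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
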