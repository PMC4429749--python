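import pytest

from mirregnet.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def sim():
    """One full synthetic dataset at generator defaults (seed 1)."""
    return simulate_all(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_config():
    """A reduced configuration for fast end-to-end CLI runs."""
    return dict(n_chromosomes=1, chromosome_length=160_000, n_mirnas=6,
                n_genes=200, coexpr_block_size=10, n_tf_pairs=2,
                n_mti_mirnas=2, n_extra_graph_genes=10)
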