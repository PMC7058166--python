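import numpy as np
import pytest

from orcevo.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One 24-taxon synthetic study shared by read-only tests."""
    cfg = SimulationConfig(n_taxa=24, motif_sub_prob_centrioles=0.2)
    return simulate_dataset(cfg, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
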