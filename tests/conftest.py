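import numpy as np
import pytest

import lorescan as ls


@pytest.fixture(scope="session")
def species_tree():
    return ls.SpeciesTree()


@pytest.fixture(scope="session")
def quartet_labels():
    """Standard leaf labels of a sturgeon/paddlefish ohnolog quartet."""
    return ("Sturgeon|sa", "Sturgeon|sb", "Paddlefish|pa", "Paddlefish|pb")


@pytest.fixture(scope="session")
def small_dataset():
    """A noise-free simulated dataset shared across tests (read-only)."""
    cfg = ls.SimConfig(n_blocks=30, genes_per_block=4, seed=5)
    return ls.simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
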