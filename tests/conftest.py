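import numpy as np
import pytest

from dupscape.simulate import SimConfig, simulate_dataset
from dupscape.species_tree import SpeciesPhylogeny


@pytest.fixture(scope="session")
def insect_tree():
    return SpeciesPhylogeny.default_insect()


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated dataset shared across read-only tests."""
    return simulate_dataset(SimConfig(n_families=25, root_len=40, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
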