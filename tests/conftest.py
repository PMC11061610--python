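import numpy as np
import pytest

from dormtrace import synthetic as syn


@pytest.fixture(scope="session")
def pot100():
    """A desk-scale founder population: 100 lineages, heterogeneous fitness."""
    return syn.simulate_pot(syn.ExpansionModel(n_barcodes=100, seed=11))


@pytest.fixture(scope="session")
def carbon_copy(pot100):
    """One 20,000-cell carbon copy split from the shared POT."""
    return syn.split_carbon_copies(pot100, 1, 20_000, seed=12)[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
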