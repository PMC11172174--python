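import numpy as np
import pytest

from hspirna.simulate import PiRNAScenario, make_te_panel, simulate_small_rna_library


@pytest.fixture(scope="session")
def te_panel():
    return make_te_panel(n_families=3, consensus_length=1500, seed=101)


@pytest.fixture(scope="session")
def small_sim(te_panel):
    """A modest library with strong planted ping-pong signal."""
    scenario = PiRNAScenario(
        te_panel=te_panel,
        pingpong_fraction=0.8,
        library_size=4000,
        contaminant_fraction=0.1,
        seed=7,
    )
    return simulate_small_rna_library(scenario)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
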