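import numpy as np
import pytest

from rmystr.panels import load_panel
from rmystr.pedigree import PedigreeGraph
from rmystr.simulate import default_founder, default_model


@pytest.fixture(scope="session")
def yfiler():
    return load_panel("YFILER")


@pytest.fixture(scope="session")
def rm13():
    return load_panel("RM13")


@pytest.fixture(scope="session")
def rm11():
    return load_panel("RM11")


@pytest.fixture(scope="session")
def both_panels(yfiler, rm13):
    return [yfiler, rm13]


@pytest.fixture(scope="session")
def model(both_panels):
    return default_model(both_panels)


@pytest.fixture(scope="session")
def founder(both_panels):
    return default_founder(both_panels)


@pytest.fixture
def rng():
    return np.random.default_rng(20161101)


@pytest.fixture
def chain_pedigree():
    """A -> B -> C paternal chain with the two ends sampled."""
    return PedigreeGraph("chain", {"A": "B", "B": "C"}, {"A", "C"})


@pytest.fixture
def brothers_pedigree():
    return PedigreeGraph("brothers", {"A": "F", "B": "F"}, {"A", "B"})
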