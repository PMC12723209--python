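import numpy as np
import pytest
from hypothesis import settings

from cardiomap.dictionary import DictionaryGrid, generate_dictionary
from cardiomap.params import CardiacTiming, SequenceParams, TissueParams

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def seq():
    return SequenceParams()


@pytest.fixture(scope="session")
def timing60():
    return CardiacTiming.from_hr(60.0)


@pytest.fixture(scope="session")
def myocardium():
    return TissueParams(t1=0.700, t1rho=0.056)


@pytest.fixture(scope="session")
def full_dictionary(seq, timing60):
    """The full 35,502-atom default-grid dictionary at HR 60."""
    return generate_dictionary(seq, timing60)


@pytest.fixture(scope="session")
def coarse_dictionary(seq, timing60):
    """A small dictionary for fast matching tests."""
    grid = DictionaryGrid(
        t1_values=np.arange(100, 1501, 50),
        t1rho_values=np.arange(10, 121, 5),
    )
    return generate_dictionary(seq, timing60, grid)
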