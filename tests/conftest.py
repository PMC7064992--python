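import numpy as np
import pytest

from gvpscan.chem_masses import default_ledger
from gvpscan.library_search import SearchParams


@pytest.fixture(scope="session")
def ledger():
    return default_ledger()


@pytest.fixture(scope="session")
def params():
    return SearchParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
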