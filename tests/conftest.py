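import numpy as np
import pytest

from lakeowt.retrieval import builtin_registry
from lakeowt.synthetic import reference_library


@pytest.fixture(scope="session")
def registry():
    return builtin_registry()


@pytest.fixture(scope="session")
def msi_lib():
    return reference_library("MSI")


@pytest.fixture(scope="session")
def olci_lib():
    return reference_library("OLCI")


@pytest.fixture()
def rng():
    return np.random.default_rng(20180401)
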