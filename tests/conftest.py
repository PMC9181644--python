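import numpy as np
import pytest

from trackrbe import ENDPOINT_PRESETS, NucleusModel


@pytest.fixture(scope="session")
def nucleus():
    """Default full-size nucleus (shared; construction does a grid search)."""
    return NucleusModel()


@pytest.fixture(scope="session")
def small_nucleus():
    """Cheap nucleus for Monte Carlo unit tests."""
    return NucleusModel(radius=2.0, height=4.0, n_domains=100)


@pytest.fixture(scope="session")
def du145():
    return ENDPOINT_PRESETS["DU145"]


@pytest.fixture(scope="session")
def rsc():
    return ENDPOINT_PRESETS["RSC_repair"]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
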