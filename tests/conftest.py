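import numpy as np
import pytest

from thermoprop import load_example_table


@pytest.fixture(scope="session")
def original_table():
    """Eight-temperature D table with the narrow regression CIs."""
    return load_example_table("original")


@pytest.fixture(scope="session")
def expanded_table():
    """Same D means with the deliberately widened CIs."""
    return load_example_table("expanded")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
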