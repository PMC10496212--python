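import numpy as np
import pytest
from hypothesis import settings

from orphanval.scenario import load_fixture

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def base():
    return load_fixture("rett_base")


@pytest.fixture(scope="session")
def lower():
    return load_fixture("rett_lower")


@pytest.fixture(scope="session")
def upper():
    return load_fixture("rett_upper")


@pytest.fixture(scope="session")
def me_too():
    return load_fixture("me_too")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
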