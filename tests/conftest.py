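import numpy as np
import pytest

from cogstack.synthetic import make_fixture


@pytest.fixture(scope="session")
def tiny_cohort():
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def null_cohort():
    return make_fixture("null")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
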