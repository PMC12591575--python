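import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from vexpect import default_grammar


@pytest.fixture(scope="session")
def grammar():
    return default_grammar()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
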