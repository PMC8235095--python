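import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def array():
    from magtremor.coils import default_array

    return default_array()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
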