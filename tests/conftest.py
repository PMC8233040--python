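import numpy as np
import pytest

import hd2speed as h


@pytest.fixture(scope="session")
def short_trajectory():
    """A 30 s synthetic trajectory shared by fast unit tests."""
    return h.generate_ou_trajectory(h.OUParams(duration=30_000.0), dt=1.0, seed=42)


@pytest.fixture(scope="session")
def fitted_tm():
    return h.TMParams()  # the fitted thalamocortical parameter set


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
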