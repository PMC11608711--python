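import logging

import numpy as np
import pytest

from psmcea import RunConfig, default_parameters
from psmcea.reconstruct import PseudoIPD
from psmcea.synthetic import paper_like_fixture

logging.getLogger("psmcea").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def values(params):
    return params.values_dict()


@pytest.fixture(scope="session")
def weibull_sample():
    """Shared censored Weibull(1.3, 2.0) sample, ~20% censoring."""
    rng = np.random.default_rng(42)
    t = 2.0 * rng.weibull(1.3, 500)
    c = rng.uniform(0, 8, 500)
    return PseudoIPD(
        times=np.minimum(t, c).clip(1e-9),
        events=(t <= c).astype(int),
    )


@pytest.fixture(scope="session")
def fixture_trial():
    return paper_like_fixture(2024)
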