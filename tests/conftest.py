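import numpy as np
import pytest

from mtgrowth import GMPCPP_PARAMS, simulate_batch
from mtgrowth.trace_stats import TipTrace


@pytest.fixture(scope="session")
def gmpcpp_batch():
    """Shared batch of GMPCPP-like growth episodes (1.5 uM, no GTPase)."""
    return simulate_batch(GMPCPP_PARAMS, 16, t_total=300.0, base_seed=9000)


@pytest.fixture(scope="session")
def gmpcpp_traces(gmpcpp_batch):
    return [TipTrace.from_trajectory(t) for t in gmpcpp_batch]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
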