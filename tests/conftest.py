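import numpy as np
import pytest

import qsdmap as q


@pytest.fixture(scope="session")
def ou_cloud():
    """2000 near-independent samples of the 1-D Ornstein–Uhlenbeck well."""
    return q.make_fixture("ou_1d", seed=5)


@pytest.fixture(scope="session")
def dw1d_cloud():
    """10^4 samples of the 1-D double well at beta = 1 (both wells visited)."""
    return q.make_fixture("doublewell_1d", seed=4)


@pytest.fixture(scope="session")
def trapped_cloud():
    """2-D double-well samples trapped in the right well at beta = 10."""
    return q.make_fixture("doublewell_2d_trapped", seed=2)


@pytest.fixture(scope="session")
def blob_cloud():
    return q.make_fixture("two_blobs", seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
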