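import numpy as np
import pytest

import wirespace as ws
from wirespace.manifold import build_wiring_space
from wirespace.metrics import wiring_distance


@pytest.fixture(scope="session")
def small_planted():
    """Planted dataset small enough for fast unit tests."""
    return ws.make_planted_dataset(60, noise_sd=0.1, ts_density=0.2, seed=7)


@pytest.fixture(scope="session")
def small_space(small_planted):
    ds = small_planted
    return build_wiring_space(ds.gd, ds.mpc, ds.ts, n_components=2, seed=7)


@pytest.fixture(scope="session")
def small_wd(small_space):
    return wiring_distance(small_space)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
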