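import numpy as np
import pytest

from rseikit import Grid, SimConfig, simulate


def make_grid(values, **kwargs):
    return Grid(np.asarray(values, dtype=np.float64), **kwargs)


@pytest.fixture(scope="session")
def sim_default():
    """One default-condition landscape shared by read-only tests."""
    return simulate(SimConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
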