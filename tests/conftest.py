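import numpy as np
import pytest

from flowamide import GPConfig, calibrate, default_space


@pytest.fixture(scope="session")
def space():
    return default_space()


@pytest.fixture(scope="session")
def params():
    """Simulator calibrated to the printed anchors (shared across the suite)."""
    return calibrate(seed=0)


@pytest.fixture(scope="session")
def noiseless(params):
    return params.replace(noise_sigma=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def fast_gp(seed=0, **kw):
    """GP config for tests: fewer restarts, instrument-noise floor."""
    kw.setdefault("n_restarts", 3)
    kw.setdefault("noise_floor", 0.005)
    return GPConfig(seed=seed, **kw)
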