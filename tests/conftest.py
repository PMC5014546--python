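import numpy as np
import pytest

import scenemeg as sm


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sensors():
    return sm.make_sensor_topographies(32, np.random.default_rng(7))


@pytest.fixture(scope="session")
def fx():
    return sm.EffectConfig()


@pytest.fixture(scope="session")
def small_dataset(fx):
    """One small two-group dataset shared by preprocessing/stats tests."""
    rng = np.random.default_rng(99)
    return sm.simulate_dataset(
        fx, rng, n_passive=5, n_active=5, n_channels=32, trials_per_cond=16,
        noise=sm.NoiseConfig(outlier_fraction=0.0),
    )
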