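import numpy as np
import pytest

from lamvar import synth


@pytest.fixture(scope="session")
def small_session():
    """One-penetration session, small enough for fast unit tests."""
    cfg = synth.default_config(seed=11, n_penetrations=1, channels_per_penetration=12,
                               n_diameters=8, trials_per_diameter=25)
    data, truth = synth.simulate_session(cfg)
    return cfg, data, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
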