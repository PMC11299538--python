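import numpy as np
import pytest

import spikespectra as ss


@pytest.fixture(scope="session")
def moderate_train():
    """Higher-rate, moderate-modulation oscillatory train (9 Hz, 41 Hz FR)."""
    params = ss.SimParams(rate_hz=41.0, m=0.4, f_osc=9.0, n_r=9, k=0.7, T=60 * 1024)
    return ss.simulate_spike_train(params, 12345), params


@pytest.fixture(scope="session")
def sparse_train():
    """Low-rate, strong-modulation oscillatory train (9 Hz, 11 Hz FR)."""
    params = ss.SimParams(rate_hz=11.0, m=0.6, f_osc=9.0, n_r=9, k=0.7, T=60 * 1024)
    return ss.simulate_spike_train(params, 999), params


@pytest.fixture(scope="session")
def poisson_train():
    """No oscillation, no recovery period: homogeneous Poisson at 20 Hz."""
    params = ss.SimParams(rate_hz=20.0, m=0.0, f_osc=10.0, n_r=0, k=0.0, T=60 * 1024)
    return ss.simulate_spike_train(params, 777), params


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
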