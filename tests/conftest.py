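import numpy as np
import pytest

from gaitnet.mvar import VARProcess
from gaitnet.simulate import ClassSpec, make_mvar_system, simulate_trial_set


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_system():
    """3-channel order-2 system with one directed edge 0 -> 1."""
    return make_mvar_system(3, 2, [(0, 1, 0.5)], seed=11)


@pytest.fixture(scope="session")
def white_process():
    """Pure-noise process (all-zero coefficients, identity covariance)."""
    return VARProcess(np.zeros((1, 3, 3)), np.eye(3))


@pytest.fixture(scope="session")
def two_class_epochs():
    """Small two-class dataset with different planted connectivity plus REST.

    4 channels, 250 Hz, 10 trials per class; MCI carries an alpha
    oscillation and a -5 uV ERP at 200 ms, IEG is theta-flavoured.
    """
    m_a = make_mvar_system(4, 2, [(0, 1, 0.5), (2, 3, 0.5)], seed=3)
    m_b = make_mvar_system(4, 2, [(1, 0, 0.5)], seed=4)
    m_r = make_mvar_system(4, 2, [], seed=5)
    specs = [
        ClassSpec("MCI", m_a, erp_amplitude=-5.0, dominant_band="alpha",
                  band_gain=2.0),
        ClassSpec("IEG", m_b, erp_amplitude=-4.0, dominant_band="theta",
                  band_gain=2.0),
        ClassSpec("REST", m_r),
    ]
    epochs, truth = simulate_trial_set(specs, 10, rate_hz=250.0, seed=42)
    return epochs, truth
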