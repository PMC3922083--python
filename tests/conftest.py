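import numpy as np
import pytest

from spikecd.boltzmann import RBMParams, random_rbm
from spikecd.calibration import TransferFit, calibrate
from spikecd.params import NeuronParams


@pytest.fixture(scope="session")
def neuron():
    """Reference neuron: C=1pF, gL=1nS, theta=100mV, tau_r=4ms, sigma=3e-11."""
    return NeuronParams()


@pytest.fixture(scope="session")
def fit(neuron):
    """Measured-and-fitted transfer curve, shared across the session."""
    f, _ = calibrate(neuron, t_sim=5.0, rng_seed=3)
    return f


@pytest.fixture(scope="session")
def table_fit():
    """Reference sigmoid-fit constants of the target configuration."""
    return TransferFit(beta=2.044e9, gamma=8808.0, tau_r=4e-3)


@pytest.fixture()
def rbm_2x2():
    rng = np.random.default_rng(11)
    return RBMParams(W=rng.normal(0, 1, (2, 2)), b_v=rng.normal(0, 1, 2),
                     b_h=rng.normal(0, 1, 2))


@pytest.fixture()
def rbm_5x5():
    return random_rbm(rng=0)
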