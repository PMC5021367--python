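import numpy as np
import pytest

from ifflkit import IFFLParams, PulseTrain


@pytest.fixture
def base_params() -> IFFLParams:
    """The reference dimensionless parameter set (beta=1.2, gamma_R=10)."""
    return IFFLParams(beta=1.2, gamma_R=10.0, gamma_o=0.0, n=110.0)


@pytest.fixture
def short_pulse_train() -> PulseTrain:
    """Counting regime: D=1 pulses at period T=4."""
    return PulseTrain(k=1, T=4.0, D=1.0, tau0=1.0)


@pytest.fixture
def long_pulse_train() -> PulseTrain:
    """Resetting regime: D=3 pulses push the intermediate over threshold."""
    return PulseTrain(k=1, T=4.0, D=3.0, tau0=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160913)
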