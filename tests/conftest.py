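import numpy as np
import pytest

from hippoexc.ephys import RampProtocol, StepProtocol
from hippoexc.simulate import NeuronModelParams, simulate_current_clamp


@pytest.fixture(scope="session")
def lif_params():
    """Reference LIF neuron: rheobase 100 pA, tau 20 ms."""
    return NeuronModelParams(r_in_mohm=200.0, c_m_pf=100.0, v_rest_mv=-70.0,
                             v_thresh_mv=-50.0, v_reset_mv=-60.0)


@pytest.fixture(scope="session")
def lif_step_set(lif_params):
    return simulate_current_clamp(lif_params, StepProtocol(10.0, 10.0, 15))


@pytest.fixture(scope="session")
def lif_ramp_set(lif_params):
    return simulate_current_clamp(lif_params, RampProtocol(peak_pa=800.0))


@pytest.fixture(scope="session")
def lif_passive_set():
    params = NeuronModelParams(r_in_mohm=150.0, c_m_pf=120.0)
    return params, simulate_current_clamp(params, StepProtocol(-50.0, 0.0, 1))
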