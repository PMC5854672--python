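import numpy as np
import pytest

from bkfit import BlockModel, GatingModel, StepProtocol

# mSlo1-like half-activation voltage at 10 uM intracellular Ca2+
MSLO1_VHALF = 30.39

# mSlo1-like charybdotoxin block rates: tau_on = 3.5 s, tau_off = 21.6 s
# at 1 uM toxin, hence k_off = 1/21.6 and k_on = (1/3.5 - 1/21.6)/1000
MSLO1_KOFF = 1.0 / 21.6
MSLO1_KON = (1.0 / 3.5 - 1.0 / 21.6) / 1000.0


@pytest.fixture
def protocol():
    """Voltage-step family -140..+140 mV in 20 mV increments on a 0.1 ms
    grid (the 100 kHz default grid is finer than single-fit tests need)."""
    return StepProtocol(sample_interval_ms=0.1)


@pytest.fixture
def coarse_protocol():
    """Same step family on a 0.1 ms grid, for Monte Carlo loops."""
    return StepProtocol(sample_interval_ms=0.1)


@pytest.fixture
def fast_gating_model():
    """Activating model whose relaxation completes well within the step,
    so steady-state extraction is exact in the noiseless limit."""
    return GatingModel(v_half=MSLO1_VHALF, kappa=-16.0, g_max=10.0,
                       e_rev=0.0, tau_params=0.5, noise_sd=0.0, seed=0)


@pytest.fixture
def mslo1_block_model():
    """Block model with mSlo1-like rates, sampled densely enough to resolve
    tau_on and with an application window long enough to reach equilibrium."""
    return BlockModel(k_on=MSLO1_KON, k_off=MSLO1_KOFF, toxin_nm=1000.0,
                      i0_pa=1000.0, t_apply_s=30.0, t_washout_s=90.0,
                      interval_s=0.5, total_s=200.0, noise_sd=0.0, seed=0)


def peak_current_pa(model: GatingModel, protocol: StepProtocol) -> float:
    """Largest noiseless steady-state current of the step family, used to
    express noise levels as a fraction of peak."""
    return max(abs(model.steady_current_pa(v)) for v in protocol.step_voltages)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
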