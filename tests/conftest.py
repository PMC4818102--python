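import numpy as np
import pytest

from ofcppf import (
    NeuronParams,
    SimulatorConfig,
    intention_weights,
    make_cursor_dynamics,
    solve_steady_state_gain,
)

DELTA = 0.005


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def dyn():
    """Decoder-style cursor dynamics (fitted persistence, velocity noise)."""
    return make_cursor_dynamics(a=0.97, w=1.0, delta=DELTA)


@pytest.fixture(scope="session")
def instant_dyn():
    """Instant-OFC dynamics: the control command sets the velocity."""
    return make_cursor_dynamics(a=0.0, w=0.0, delta=DELTA)


@pytest.fixture(scope="session")
def intent_gain(instant_dyn):
    return solve_steady_state_gain(instant_dyn, intention_weights())


@pytest.fixture
def tuned_unit():
    return NeuronParams(baseline=np.log(20.0), velocity_coeffs=np.array([0.1, 0.0]))


@pytest.fixture
def fast_config():
    """A small closed-loop configuration for quick end-to-end checks."""
    return SimulatorConfig()
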