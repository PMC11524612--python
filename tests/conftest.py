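import numpy as np
import pytest

from cldyn import ModelParams, NeuronState
from cldyn.bifurcation import continue_branch, find_fixed_point


@pytest.fixture(scope="session")
def params_conservative():
    """Reference parameters with bath diffusion disabled (intrinsic dynamics)."""
    return ModelParams(eps_k=0.0)


@pytest.fixture(scope="session")
def rest_597(params_conservative):
    """Stationary family member at [Cl-]i = 5.97 mM (the low-chloride resting state)."""
    guess = NeuronState.with_steady_gating(V=-70.0, K_o=3.0, Na_i=20.0, Cl_i=5.97)
    return find_fixed_point(guess, params_conservative, clamp=("Cl_i", 5.97))


@pytest.fixture(scope="session")
def cl_branch(params_conservative):
    """Fixed-point branch in [Cl-]i over 5-20 mM (no bath, no GABA)."""
    guess = NeuronState.with_steady_gating(V=-76.5, K_o=2.4, Na_i=21.7, Cl_i=5.0)
    return continue_branch("Cl_i", (5.0, 20.0), guess, params_conservative, step0=0.1)


@pytest.fixture(scope="session")
def random_states():
    """Valid random states spanning the physiological region (seeded)."""
    rng = np.random.default_rng(20240308)
    states = []
    for _ in range(100):
        states.append(NeuronState.with_steady_gating(
            V=rng.uniform(-90.0, 0.0), K_o=rng.uniform(2.0, 12.0),
            Na_i=rng.uniform(12.0, 30.0), Cl_i=rng.uniform(3.0, 20.0)))
    return states


def sweep_initial(cl0: float) -> NeuronState:
    """Initial condition of the intrinsic-dynamics sweep (only Cl varies)."""
    return NeuronState.with_steady_gating(V=-70.74, K_o=2.99, Na_i=20.06, Cl_i=cl0)
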