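import numpy as np
import pytest

from pflswitch import presets
from pflswitch.params import KineticParameters, SystemState


@pytest.fixture(scope="session")
def dox_ref() -> KineticParameters:
    """Reference dox-induction model (bistable, reversible at default
    feedback strength)."""
    return presets.load_params("dox_reference")


@pytest.fixture(scope="session")
def mrc5() -> KineticParameters:
    return presets.load_params("mrc5")


@pytest.fixture(scope="session")
def imr90() -> KineticParameters:
    return presets.load_params("imr90")


@pytest.fixture(scope="session")
def injection() -> KineticParameters:
    """Dermal-fibroblast exogenous-TNC injection model."""
    return presets.load_params("dermal_injection")


@pytest.fixture(scope="session")
def open_cascade(dox_ref) -> KineticParameters:
    """Feedback-ablated control (v_feedback = 0): an open cascade with a
    unique steady state at every stimulus."""
    return dox_ref.replace(v_feedback=0.0)


def random_valid_params(rng: np.random.Generator) -> KineticParameters:
    """A random parameter set within broad physical bounds, for property
    tests that must hold on any valid model."""
    def lu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    return KineticParameters(
        basal_Tw=lu(1e-4, 0.1), basal_P=lu(1e-4, 0.1), basal_T=lu(1e-4, 0.1),
        vmax_dox=lu(1, 20), km_dox=lu(0.3, 3), n_dox=1.0,
        v_feedback=lu(1, 60), km_feedback=lu(1, 10), n_feedback=float(rng.integers(1, 4)),
        vmax_TwP=lu(1, 10), km_TwP=lu(2, 20), n_TwP=2.0,
        vmax_PT=lu(1, 10), km_PT=lu(2, 15), n_PT=2.0,
        deg_Tw=lu(0.2, 2), deg_P=lu(0.2, 2), deg_T=lu(0.2, 2),
    )


def grid27(params: KineticParameters) -> list[SystemState]:
    """A 3x3x3 grid of initial conditions spanning the reachable state box."""
    ub = params.production_bound()
    states = []
    for fx in (0.0, 0.5, 1.0):
        for fy in (0.0, 0.5, 1.0):
            for fz in (0.0, 0.5, 1.0):
                states.append(SystemState(fx * ub[0], fy * ub[1], fz * ub[2]))
    return states
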