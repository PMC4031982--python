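import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rheotaxis import FlowProtocol, ModelParams

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def params() -> ModelParams:
    """Central parameter set: human sperm at low viscosity."""
    return ModelParams(V=50.0, alpha=0.3, beta=0.075, chi=+1, D=0.25,
                       A=10.0, ell=60.0, h_adv=10.0)


@pytest.fixture
def achiral_params() -> ModelParams:
    """Weakly chiral (bull-like) swimmer: chi = 0."""
    return ModelParams(V=50.0, alpha=0.3, beta=0.075, chi=0, D=0.25,
                       A=10.0, ell=60.0, h_adv=10.0)


@pytest.fixture
def steady_flow() -> FlowProtocol:
    return FlowProtocol(gamma_dot=2.5)


def combined_se(se_a: float, se_b: float) -> float:
    return float(np.hypot(se_a, se_b))
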