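import pytest

from dexpk.model_core import DEFAULT_THETA, PKParameters
from dexpk.synthetic_data import (
    DEFAULT_OMEGA,
    DEFAULT_RESIDUAL,
    OmegaSpec,
    ResidualSpec,
    design_library,
    simulate_trial,
)


@pytest.fixture(scope="session")
def final_params() -> PKParameters:
    """Individual parameters equal to the standard-subject typical values."""
    return PKParameters(cl=0.897, v1=25.2, v2=34.4, v3=65.4, q2=1.68, q3=0.62)


@pytest.fixture(scope="session")
def small_trial():
    """A 20-subject five-design trial with full variability, fixed seed."""
    return simulate_trial(
        DEFAULT_THETA, DEFAULT_OMEGA, DEFAULT_RESIDUAL, design_library(), 20, seed=42
    )


@pytest.fixture(scope="session")
def adult_trial_one_eta():
    """Adults with a single CL random effect and moderate noise."""
    omega = OmegaSpec(omega2={"cl": 0.1})
    residual = ResidualSpec(theta_ruv_cv=0.15, theta_ruv_sd=0.004)
    ds = simulate_trial(
        DEFAULT_THETA, omega, residual, design_library(["rolle"]), 8, seed=7
    )
    return ds, omega, residual
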