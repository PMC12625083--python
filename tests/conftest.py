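import numpy as np
import pytest

from cuidose.mbma import BSVParams, FitOptions, FitResult, ResidualError
from cuidose.pk_twocmt import DoseEvent, PKParams


@pytest.fixture(scope="session")
def tdm1_params() -> PKParams:
    """Fitted T-DM1 structural parameters used as generating truth."""
    return PKParams(CL=0.809, Vc=3.283, Vp=0.748, Q=1.120)


@pytest.fixture(scope="session")
def tdxd_params() -> PKParams:
    return PKParams(CL=0.585, Vc=2.785, Vp=1.243, Q=0.652)


@pytest.fixture(scope="session")
def tdm1_dose() -> DoseEvent:
    """3.6 mg/kg at the observed 69.4 kg median weight, 90-min infusion."""
    return DoseEvent(dose_mg=3.6 * 69.4, infusion_duration_h=1.5)


def make_fit_result(pk: PKParams, bsv: BSVParams | None = None,
                    error: ResidualError | None = None) -> FitResult:
    """FitResult holding known parameter values, for tests that exercise
    downstream stages without re-estimating."""
    return FitResult(
        pk=pk,
        bsv=bsv or BSVParams(omega_CL=0.334, omega_Vc=0.221, rho=0.825),
        error=error or ResidualError(a=2633.766, b=0.430),
        rse={}, loglik=0.0, convergence=True, n_arms_used=0,
        options=FitOptions(),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240501)
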