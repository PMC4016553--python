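import pytest

from hcc_alloc import CohortParams, ModelParams


@pytest.fixture(scope="session")
def baseline_model() -> ModelParams:
    """Default scenario: alpha0=0.048, alpha1=2, delta1=0.3, delta2=0.006, lam=0.3, T=5."""
    return ModelParams()


@pytest.fixture(scope="session")
def baseline_cohort() -> CohortParams:
    """Default waiting list: N=1500 patients, F=500 grafts, Milan cutoff 5 cm."""
    return CohortParams()


@pytest.fixture(scope="session")
def flat_hazard_model() -> ModelParams:
    """Hazard curves that never cross for s > 0 (transplantation never helps).

    With delta1=0.02 the initial slope of the non-transplanted hazard,
    alpha0*delta1 = 0.00096, is below the transplanted slope delta2 = 0.006,
    so the mortality curve is monotone increasing in the cutoff.
    """
    return ModelParams(delta1=0.02)
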