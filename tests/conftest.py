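import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small generated cohort shared across tests (n=800, fixed seed)."""
    from neurocvr.cohort import default_params, generate_cohort

    return generate_cohort(default_params(800), seed=321)


@pytest.fixture(scope="session")
def tiny_matrix(tiny_cohort):
    from neurocvr.preprocess import build_model_matrix

    mat, _ = build_model_matrix(tiny_cohort)
    return mat


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
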