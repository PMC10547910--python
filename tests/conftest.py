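import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from thalmr import cohort

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_cohort_50k():
    """One large default-model cohort shared by the slower property tests."""
    return cohort.generate_cohort(cohort.default_published_params(50_000, seed=20230))


@pytest.fixture()
def rng():
    return np.random.default_rng(991)
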