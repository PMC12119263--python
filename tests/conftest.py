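import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from qcascreen import cohort, scales

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cohort():
    return cohort.generate_cohort(cohort.CohortConfig(n_respondents=3063, seed=1))


@pytest.fixture(scope="session")
def scored_cohort(default_cohort):
    return scales.score_cohort(default_cohort)


@pytest.fixture(scope="session")
def big_cohort():
    """Large draw for marginal-fidelity checks."""
    return cohort.generate_cohort(cohort.CohortConfig(n_respondents=100_000, seed=2))
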