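import pytest
from hypothesis import HealthCheck, settings

import comosim as cs

settings.register_profile(
    "det", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("det")


@pytest.fixture(scope="session")
def truth():
    return cs.default_truth()


@pytest.fixture(scope="session")
def small_cohort(truth):
    """~45k person-years under the default truth (session-wide)."""
    spec = cs.default_spec(6000, seed=11, truth=truth)
    return cs.generate_cohort(spec)


@pytest.fixture(scope="session")
def fitted_models(small_cohort):
    return cs.fit_transition_models(small_cohort)


@pytest.fixture()
def categorizer():
    return cs.CovariateCategorizer()
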