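import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    from steroidpanel import default_cohort_config, generate_cohort

    return generate_cohort(default_cohort_config(seed=11))


@pytest.fixture(scope="session")
def cycle_series():
    from steroidpanel import default_cycle_config, generate_cycle_series

    return generate_cycle_series(default_cycle_config(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
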