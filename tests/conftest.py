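import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-parameter cohort shared across tests."""
    from commonpool.agent_models import CohortSpec
    from commonpool.experiment_runner import RunConfig, simulate_cohort

    config = RunConfig(cohort=CohortSpec(n_per_group=4, seed=202), n_boot=25)
    trials, outcomes = simulate_cohort(config)
    return config, trials, outcomes
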