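import pytest
from hypothesis import HealthCheck, settings

from exposuremc import CohortConfig, build_table1_fixture
from exposuremc.regression import classification_table

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

TARGET_OUTCOMES = ["go_nogo_speed", "groton_maze_errors", "stroop_ab_ratio"]


@pytest.fixture(scope="session")
def fixture_cohort():
    """Deterministic cohort calibrated to the published exposure summaries."""
    return build_table1_fixture()


@pytest.fixture(scope="session")
def fixture_classification(fixture_cohort):
    return classification_table(fixture_cohort)


@pytest.fixture(scope="session")
def target_config():
    """Default config restricted to the three headline outcomes."""
    return CohortConfig().restricted_to(TARGET_OUTCOMES)
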