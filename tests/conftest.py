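import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def cohort59():
    """Default-size synthetic cohort shared across tests (fixed seed)."""
    from creapew import generate_cohort

    return generate_cohort(59, 7)


@pytest.fixture(scope="session")
def mass_balance59(cohort59):
    from creapew import mass_balance_table

    return mass_balance_table(cohort59.sessions, cohort59.patients)
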