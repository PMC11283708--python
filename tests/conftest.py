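import pytest
from hypothesis import HealthCheck, settings

from ssbtax import synth
from ssbtax.demand import ScenarioConfig, TaxPolicy
from ssbtax.engine import ScenarioEngine

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sparams():
    return synth.SyntheticParams(seed=123)


@pytest.fixture(scope="session")
def cohorts(sparams):
    return synth.generate_cohorts(sparams)


@pytest.fixture(scope="session")
def epi(sparams):
    return synth.generate_epi(sparams)


@pytest.fixture(scope="session")
def engine(cohorts, epi, sparams):
    return ScenarioEngine(
        cohorts,
        epi,
        rr_schedule=synth.default_rr_schedule(),
        econ=synth.default_econ(sparams),
    )


@pytest.fixture(scope="session")
def presets():
    return synth.reference_scenarios()


@pytest.fixture(scope="session")
def null_config():
    """A zero-rate tax: every downstream change must be exactly zero."""
    return ScenarioConfig(name="null", policy=TaxPolicy(rate=0.0, pass_through=0.82))
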