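import pytest
from hypothesis import settings

from stoppstart.criteria import load_catalog
from stoppstart.simulate import CohortConfig, generate

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def small_cohort():
    """A 50-patient synthetic cohort shared across tests."""
    return generate(CohortConfig(n=50, seed=7))


@pytest.fixture(scope="session")
def medium_cohort():
    """A 2,000-patient cohort for distributional checks."""
    return generate(CohortConfig(n=2000, seed=11))
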