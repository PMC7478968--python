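import pytest
from hypothesis import HealthCheck, settings

from crispre import datasets

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def grlb_exp():
    return datasets.grlb()


@pytest.fixture(scope="session")
def grlc_exp():
    return datasets.grlc()


@pytest.fixture(scope="session")
def kif1a_exp():
    return datasets.kif1a()


@pytest.fixture(scope="session")
def far1_exp():
    return datasets.far1()


@pytest.fixture(scope="session")
def dync_combined_exp():
    return datasets.dync1li1_combined()


@pytest.fixture(scope="session")
def sim_target():
    """A synthetic reference + guide + site for simulator tests."""
    ref, guide, site = datasets.make_synthetic_target("simref", 123)
    return ref, guide, site
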