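import pytest
from hypothesis import HealthCheck, settings

from hypoecon.params import default_parameters

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def us_bundle():
    return default_parameters("US")


@pytest.fixture(scope="session")
def ca_bundle():
    return default_parameters("Canada")


@pytest.fixture(scope="session", params=["US", "Canada"])
def bundle(request, us_bundle, ca_bundle):
    return us_bundle if request.param == "US" else ca_bundle
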