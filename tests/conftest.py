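import pytest
from hypothesis import HealthCheck, settings

from cdsprep import ClassificationPolicy, default_formulary

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=200,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def formulary():
    return default_formulary()


@pytest.fixture(scope="session")
def policy():
    return ClassificationPolicy()
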