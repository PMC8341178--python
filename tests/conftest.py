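import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from lusucea import default_parameters  # noqa: E402


@pytest.fixture(scope="session")
def base_params():
    return default_parameters()


@pytest.fixture()
def params(base_params):
    """A mutable copy of the shipped base case."""
    return base_params.copy_deep()
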