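import pytest
from hypothesis import HealthCheck, settings

from lgscea import EffectivenessPolicy, load_parameters

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def base_inputs():
    """Bundled base-case probabilities and costs."""
    return load_parameters()


@pytest.fixture(scope="session")
def atonic_inputs():
    """Atonic-seizure scenario probabilities (costs shared with base)."""
    return load_parameters(scenario="atonic")


@pytest.fixture(scope="session")
def reference_policy():
    return EffectivenessPolicy.preset("reference")


@pytest.fixture(scope="session")
def strict_policy():
    return EffectivenessPolicy.preset("strict")
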