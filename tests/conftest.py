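import pytest
from hypothesis import HealthCheck, settings

from volratio import DEFAULT_CV, symmetric_thresholds

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_thresholds():
    """The clinical default: 95% thresholds at the ~15% volumetry CV."""
    return symmetric_thresholds(DEFAULT_CV)
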