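import pytest
from hypothesis import HealthCheck, settings

import adaptfuse as af

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table3() -> af.ReliabilityTable:
    """Packaged per-activity recognition-correctness table."""
    return af.load_reliability_table("table3")


@pytest.fixture(scope="session")
def table4() -> af.ReliabilityTable:
    """Packaged per-volunteer recognition-correctness table."""
    return af.load_reliability_table("table4")
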