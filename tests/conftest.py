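import pytest
from hypothesis import HealthCheck, settings

from qctcount.simdata import demo_assay, pools_from_config

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def assay():
    """Compact two-pool demonstration assay shared across the suite."""
    return demo_assay()


@pytest.fixture(scope="session")
def pools(assay):
    return pools_from_config(assay)
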