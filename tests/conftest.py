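import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from hamtbs import synthetic_panel  # noqa: E402


@pytest.fixture(scope="session")
def small_panel():
    """Two short amplicons, 3 CpGs and 10 CHH cytosines each."""
    return synthetic_panel(n_amplicons=2, n_cpgs=3, n_chh=10, length=200, seed=1)


@pytest.fixture(scope="session")
def std_panel():
    """Validation-scale panel: 7 amplicons x 5 CpGs, 20 CHH each."""
    return synthetic_panel(n_amplicons=7, n_cpgs=5, n_chh=20, length=330, seed=11)
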