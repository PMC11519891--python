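import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from snpharmony import Coding, FixtureSpec, make_registry  # noqa: E402


@pytest.fixture(scope="session")
def small_spec() -> FixtureSpec:
    return FixtureSpec(n_snps=30, n_samples=8, seed=123)


@pytest.fixture(scope="session")
def small_registry(small_spec):
    registry, _ = make_registry(small_spec)
    return registry


@pytest.fixture
def reference_variants(small_registry):
    """The two always-present conversion reference SNPs."""
    return (small_registry.get("DU186191_327.1"),
            small_registry.get("OAR1_103790218.1"))
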