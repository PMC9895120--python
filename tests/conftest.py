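import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from mirledit import generate_reference  # noqa: E402
from mirledit.examples import nine_category_sites  # noqa: E402


@pytest.fixture(scope="session")
def small_reference():
    """Three random hairpins (both arms each), no decoys."""
    return generate_reference(3, (62, 90), seed=1, n_decoys=0)


@pytest.fixture(scope="session")
def category_fixture():
    return nine_category_sites()
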