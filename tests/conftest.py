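import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from sheetmerge.fixtures import worked_example_fixture  # noqa: E402


@pytest.fixture(scope="session")
def worked_example():
    """Sheets A/B, the collocate lexicon, and the true grouping of the
    gender/sex/grade example."""
    return worked_example_fixture()
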