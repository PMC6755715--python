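import pytest
from hypothesis import HealthCheck, settings

from lexner import NormalizationConfig, examples

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=150,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def config():
    return NormalizationConfig()


@pytest.fixture
def example_lexicon():
    return examples.compiled()


@pytest.fixture
def example_links():
    return examples.links_table()
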