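import pytest
from hypothesis import settings

from kumascale import (
    all_normal_assessment,
    all_worst_assessment,
    example_moderate_assessment,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def vignette():
    """The moderate-polyneuropathy worked example (revised 16.5 / original
    17 points)."""
    return example_moderate_assessment()


@pytest.fixture
def all_normal():
    return all_normal_assessment()


@pytest.fixture
def all_worst():
    return all_worst_assessment()
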