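import numpy as np
import pytest
from hypothesis import settings

from combindex import reference

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def acarbose():
    return reference.ACARBOSE


@pytest.fixture(scope="session")
def kaempferol():
    return reference.KAEMPFEROL


@pytest.fixture(scope="session")
def propolis():
    return reference.PROPOLIS


@pytest.fixture(scope="session")
def ap_rows():
    """Published per-level results for the acarbose+propolis pairing."""
    return reference.combination_rows("acarbose+propolis")


@pytest.fixture(scope="session")
def ak_rows():
    """Published per-level results for the acarbose+kaempferol pairing."""
    return reference.combination_rows("acarbose+kaempferol")
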