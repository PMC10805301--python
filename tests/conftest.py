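import pytest

from edac.core import CodeRegistry
from edac.synthetic import SYNTHETIC_REGISTRY_CODES, reference_fixture


@pytest.fixture(scope="session")
def registry():
    return CodeRegistry.from_codes(SYNTHETIC_REGISTRY_CODES)


@pytest.fixture(scope="session")
def fixture_table():
    """The frozen 160-visit reference concordance table."""
    return reference_fixture()


@pytest.fixture(scope="session")
def fixture_pairs(fixture_table):
    """The reference table expanded to anonymous judgement pairs."""
    return fixture_table.to_pairs()
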