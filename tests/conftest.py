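import pytest
from hypothesis import settings

from coenzsites import load_registry
from coenzsites.synthetic_data import make_minimal_fixture

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def minimal_fixture():
    """The tiny hand-written bundle and its hand-computed expectations."""
    return make_minimal_fixture()
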