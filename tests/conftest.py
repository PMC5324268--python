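import pytest

from rinvar.fixtures import make_helix, shipped_fixtures


@pytest.fixture(scope="session")
def fixture_set():
    """The shipped synthetic structures with their ground-truth contact maps."""
    return shipped_fixtures()


@pytest.fixture(scope="session")
def ala_helix():
    return make_helix("AAAAAAAAAA")


@pytest.fixture(scope="session")
def mixed_helix():
    return make_helix("AVLIFSTYNQKEDRH")
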