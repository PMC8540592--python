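import pytest

from openrds.energy import NearestNeighborBackend
from openrds.score import ScoreParameters


@pytest.fixture(scope="session")
def backend():
    """One memoizing backend per session: folds are cached across tests."""
    return NearestNeighborBackend()


@pytest.fixture(scope="session")
def params():
    return ScoreParameters()
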