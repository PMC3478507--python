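import numpy as np
import pytest

from groundshine.tables import load_published_tables


@pytest.fixture(scope="session")
def published_tables():
    """The packaged printed coefficient tables (adult, baby)."""
    return load_published_tables()


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
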