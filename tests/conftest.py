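import numpy as np
import pytest

from kidneyvol.phantom import PhantomConfig, generate_subject


@pytest.fixture(scope="session")
def desk_config():
    return PhantomConfig.desk_scale(seed=1)


@pytest.fixture(scope="session")
def desk_subject(desk_config):
    """One clean desk-scale phantom, shared read-only across tests."""
    return generate_subject(desk_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
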