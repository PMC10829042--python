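import numpy as np
import pytest

from dsca.model import ModelSpec, build_model
from dsca.pipeline import tiny_corpus


@pytest.fixture(scope="session")
def tiny_records():
    """Eight 64×64 striped-field tiles from one synthetic scene."""
    return tiny_corpus(n_tiles=8, tile_size=64, seed=0)


@pytest.fixture(scope="session")
def reduced_model():
    return build_model(ModelSpec.reduced(), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240117)
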