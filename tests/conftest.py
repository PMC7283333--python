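import numpy as np
import pytest

from nucleotrace import phantoms


@pytest.fixture(scope="session")
def codebook():
    return phantoms.gen_codebook(10, seed=3)


@pytest.fixture(scope="session")
def scores50():
    return phantoms.synthetic_compartment_scores()


@pytest.fixture(scope="session")
def small_scene():
    """9-cell synthetic field of view shared across imaging tests."""
    return phantoms.gen_scene(n_cells=9, fov_shape=(512, 512, 10), seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
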