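import numpy as np
import pytest

import cnescreen as cs


@pytest.fixture(scope="session")
def fixture_tree():
    """12-leaf tree: 10 limbed species, 2-species loss clade, depth 0.75."""
    return cs.generate_fixture_tree(10, 2, 0.75, seed=7)


@pytest.fixture(scope="session")
def scattered_tree():
    """14-leaf tree with 4 independently placed loss lineages."""
    return cs.generate_fixture_tree(10, 4, 0.9, seed=3, scattered=True)


@pytest.fixture(scope="session")
def screen_config(fixture_tree):
    return cs.ScreenConfig.from_tree(fixture_tree)


@pytest.fixture(scope="session")
def motif_library():
    return cs.generate_motif_library(20, seed=2)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
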