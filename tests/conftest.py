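import numpy as np
import pytest

from rotshift import phylo_core, synthetic_data


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); height 2, ultrametric."""
    return phylo_core.tree_from_string("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced_four_tree():
    return phylo_core.tree_from_string("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def unit_tree_200():
    """200-tip simulated ultrametric tree rescaled to height 1 (shared, read-only)."""
    tree = synthetic_data.simulate_tree(200, seed=4242)
    return phylo_core.rescale_height(tree, 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
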