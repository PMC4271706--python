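import numpy as np
import pytest

from biomepool import parse_newick
from biomepool.simulate import simulate_bd_tree


@pytest.fixture
def cherry():
    return parse_newick("(A:1,B:1);")


@pytest.fixture
def three_tip():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def four_tip():
    return parse_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")


def random_trees(n_trees, n_tips, seed, birth=0.2, death=0.0):
    return [simulate_bd_tree(birth, death, n_tips, seed=seed + k)
            for k in range(n_trees)]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)
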