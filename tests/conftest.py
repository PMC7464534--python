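import numpy as np
import pytest

from msatphylo.phylo_core import read_newick
from msatphylo.synthetic_data import simulate_bd_tree


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def cherry():
    return read_newick("(A:1,B:1);")[0]


@pytest.fixture
def three_taxon():
    return read_newick("((A:1,B:1):1,C:2);")[0]


@pytest.fixture(scope="session")
def bd_tree_64():
    rng = np.random.default_rng(11)
    return simulate_bd_tree(64, 0.05, 0.01, rng)


@pytest.fixture(scope="session")
def bd_tree_128():
    rng = np.random.default_rng(12)
    return simulate_bd_tree(128, 0.05, 0.01, rng)


def random_dna(rng, n, gc=0.5, p_ambig=0.0):
    probs = [(1 - gc) / 2 * (1 - p_ambig), gc / 2 * (1 - p_ambig),
             gc / 2 * (1 - p_ambig), (1 - gc) / 2 * (1 - p_ambig), p_ambig]
    return "".join(np.array(list("ACGTN"))[rng.choice(5, size=n, p=probs)])
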