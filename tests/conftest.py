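import numpy as np
import pytest

from synbold.corpus_io import DependencyParse, parse_bracketed
from synbold.synthetic_data import SimulationConfig, sample_trees

#: the worked-example sentence "Mary eats apples daily"
T1_BRACKETING = "(S (NP Mary) (VP (VP eats (NP apples)) (ADVP daily)))"

#: the same sentence with a POS wrapper around every terminal
T1_POS_WRAPPED = (
    "(S (NP (NNP Mary)) (VP (VP (VBZ eats) (NP (NNS apples))) "
    "(ADVP (RB daily))))"
)


@pytest.fixture
def t1():
    return parse_bracketed(T1_BRACKETING)


@pytest.fixture
def t1_dep():
    # "eats" is the root; Mary, apples and daily all depend on it
    return DependencyParse(head=[2, 0, 2, 2])


@pytest.fixture
def t1_pos():
    return parse_bracketed(T1_POS_WRAPPED)


@pytest.fixture(scope="session")
def tree_suite():
    """300 random grammar-sampled trees with dependencies for unit tests
    (the acceptance suite runs the full 1,000)."""
    cfg = SimulationConfig(seed=7, min_length=2, max_length=40)
    return sample_trees(cfg, n=300)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
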