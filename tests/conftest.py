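import dendropy
import numpy as np
import pytest

from retroprev import pgls, simulate


@pytest.fixture
def three_tip_tree():
    return dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")


@pytest.fixture(scope="session")
def yule_tree_50():
    return simulate.simulate_tree(50, seed=42)


@pytest.fixture(scope="session")
def yule_cov_50(yule_tree_50):
    return pgls.vcv_from_tree(yule_tree_50)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
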