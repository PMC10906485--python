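import numpy as np
import pytest

from birdacuity import parse_newick, simulate_dataset, SyntheticParams


@pytest.fixture
def worked_tree():
    """Three-taxon tree whose Brownian covariance is known by hand."""
    return parse_newick("((A:1,B:1):0.5,C:1.5);")


@pytest.fixture
def star_tree_30():
    return parse_newick("(" + ",".join(f"t{i}:2" for i in range(1, 31)) + ");")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset shared across tests."""
    return simulate_dataset(SyntheticParams(seed=4242))
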