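import numpy as np
import pytest

from cochlevo import phylo_io, synthetic_data


@pytest.fixture
def cherry():
    """Two-tip ultrametric tree, both depths 1."""
    return phylo_io.read_newick("(A:1,B:1):0;")


@pytest.fixture
def three_tip():
    """((A:1,B:1):1,C:2) — ultrametric, depth 2."""
    return phylo_io.read_newick("((A:1,B:1):1,C:2):0;")


@pytest.fixture
def four_tip_symmetric():
    """((A:1,B:1):1,(C:1,D:1):1) — symmetric, depth 2."""
    return phylo_io.read_newick("((A:1,B:1):1,(C:1,D:1):1):0;")


@pytest.fixture(scope="session")
def yule50():
    return synthetic_data.simulate_yule_tree(50, 1.0, seed=42)


@pytest.fixture(scope="session")
def balanced64():
    return synthetic_data.balanced_tree(64, 10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
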