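import numpy as np
import pytest
from hypothesis import settings

# property tests must be reproducible run-to-run
settings.register_profile("derandomized", derandomize=True)
settings.load_profile("derandomized")

from slp_biogeo.simulate import SimConfig, make_benchmark, simulate_tree
from slp_biogeo.tree import Phylogeny, read_newick


@pytest.fixture(scope="session")
def balanced16():
    """Balanced 16-tip ultrametric tree, unit branch lengths."""
    s = "((((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1):1," \
        "(((I:1,J:1):1,(K:1,L:1):1):1,((M:1,N:1):1,(O:1,P:1):1):1):1);"
    return read_newick(s, from_string=True)


@pytest.fixture(scope="session")
def yule50():
    return simulate_tree(SimConfig(n_tips=50, seed=101))


@pytest.fixture(scope="session")
def bench300():
    """A mid-size end-to-end synthetic benchmark (liability mode)."""
    return make_benchmark(SimConfig(n_tips=300, seed=11, signal_sd=2.0))


def star_tree(n, branch=1.0):
    parent = np.array([n] * n + [-1])
    length = np.array([branch] * n + [0.0])
    return Phylogeny(parent, length, [f"t{i:03d}" for i in range(n)])


@pytest.fixture(scope="session")
def star100():
    return star_tree(100)
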