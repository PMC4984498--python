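import numpy as np
import pytest

from sdmevol import synthetic_data as syn
from sdmevol import treeio


@pytest.fixture(scope="session")
def balanced4():
    """Symmetric 4-tip tree with a clean root split."""
    return treeio.read_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def tree3():
    return treeio.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def yule100():
    return syn.simulate_bd_tree(syn.BDParams(0.1, 0.0, 100, seed=42))


@pytest.fixture(scope="session")
def turtle_fixture():
    return syn.make_fixture("turtle-like", 87, seed=7)


@pytest.fixture(scope="session")
def lizard_fixture():
    return syn.make_fixture("lizard-like", 300, seed=7)


def random_binary_tree(rng: np.random.Generator, n_tips: int) -> treeio.Phylogeny:
    """Random topology with iid branch lengths (not ultrametric); for oracles."""
    parts = [(f"t{i}", None) for i in range(n_tips)]
    b = treeio._Builder()
    ids = [b.add_tip(lab, float(rng.uniform(0.1, 2.0))) for lab, _ in parts]
    while len(ids) > 2:
        i, j = sorted(rng.choice(len(ids), size=2, replace=False))
        a = ids.pop(j)
        c = ids.pop(i)
        ids.append(b.add_internal([c, a], float(rng.uniform(0.1, 2.0))))
    root = b.add_internal(ids, 0.0)
    return b.build(root)
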