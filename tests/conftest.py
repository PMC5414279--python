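import numpy as np
import pytest

from phyloniche import PhyloTree, read_newick
from phyloniche.simulate import simulate_tree


@pytest.fixture
def two_tip_tree() -> PhyloTree:
    return read_newick("(A:1,B:1);")


@pytest.fixture
def three_tip_tree() -> PhyloTree:
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree() -> PhyloTree:
    return read_newick("(A:1,B:1,C:1);")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_yule_tree(n: int, seed: int) -> PhyloTree:
    return simulate_tree(n, birth_rate=1.0, seed=seed)


def shared_path_covariance_oracle(tree: PhyloTree) -> np.ndarray:
    """Brute-force Brownian covariance: per tip pair, sum the branch lengths
    of edges common to both root paths (set intersection, no MRCA logic)."""
    d = tree.dendropy_tree
    edges = {}
    for node in d.preorder_node_iter():
        if node is d.seed_node:
            edges[id(node)] = []
        else:
            edges[id(node)] = edges[id(node.parent_node)] + [
                (id(node), node.edge.length)
            ]
    leaf_edges = {
        leaf.taxon.label: dict(edges[id(leaf)]) for leaf in d.leaf_node_iter()
    }
    labels = tree.tip_labels
    C = np.zeros((len(labels), len(labels)))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            shared = set(leaf_edges[a]) & set(leaf_edges[b])
            C[i, j] = sum(leaf_edges[a][e] for e in shared)
    return C
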