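import numpy as np
import pytest

import its2sim as it


@pytest.fixture(scope="session")
def bundle():
    return it.default_substitution_models()


@pytest.fixture(scope="session")
def jc4():
    """Jukes-Cantor: uniform exchangeabilities and frequencies."""
    return it.build_gtr_rate_matrix(np.ones((4, 4)), np.full(4, 0.25))


@pytest.fixture(scope="session")
def ancestor():
    return it.generate_ancestor(it.AncestorSpec(seed=1))


def random_gtr(rng: np.random.Generator, k: int = 4):
    """A random valid GTR model (positive exchangeabilities/frequencies)."""
    s = rng.uniform(0.1, 2.0, size=(k, k))
    s = (s + s.T) / 2
    pi = rng.dirichlet(np.full(k, 5.0))
    return it.build_gtr_rate_matrix(s, pi)


def random_binary_tree(rng: np.random.Generator, n: int, min_bl=0.05, max_bl=0.5):
    """Random unrooted binary topology with random branch lengths."""
    from its2sim.trees import PhyloTree, TreeNode

    nodes = [TreeNode(label=f"t{i + 1}") for i in range(n)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        for x in (a, b):
            x.length = rng.uniform(min_bl, max_bl)
        merged = TreeNode(children=[b, a])
        nodes = [nodes[x] for x in range(len(nodes)) if x not in (i, j)] + [merged]
    for x in nodes:
        x.length = rng.uniform(min_bl, max_bl)
    return PhyloTree(TreeNode(children=nodes))
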