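import numpy as np
import pytest

from phylotox import (
    SimulationScenario,
    parse_newick,
    simulate_venom_dataset,
    simulate_yule_tree,
)


@pytest.fixture
def three_taxon():
    return parse_newick("((A:1,B:1):0.5,C:1.5);")


@pytest.fixture
def two_taxon():
    return parse_newick("(A:1,B:1);")


@pytest.fixture(scope="session")
def yule50():
    return simulate_yule_tree(50, seed=7)


@pytest.fixture(scope="session")
def venom_default():
    """Paper-like synthetic dataset: 52 species, 10 real + 15 decoy families."""
    return simulate_venom_dataset(SimulationScenario(seed=0))


def brute_force_vcv(tree, scale=False):
    """Shared path length via explicit root-to-tip node-path intersection."""
    tips = list(tree.tip_indices)
    paths = []
    for t in tips:
        p = []
        node = int(t)
        while node >= 0:
            p.append(node)
            node = int(tree.parent[node])
        paths.append(set(p))
    n = len(tips)
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            shared = paths[i] & paths[j]
            C[i, j] = sum(
                tree.lengths[k] for k in shared if tree.parent[k] >= 0
                and tree.parent[k] in shared
            )
    if scale:
        C = C / tree.height
    return C


def brute_force_patristic(tree):
    """Patristic distances by summing branch lengths along explicit paths."""
    tips = list(tree.tip_indices)
    n = len(tips)
    D = np.zeros((n, n))
    depths = tree.depths()
    C = brute_force_vcv(tree)
    for i in range(n):
        for j in range(n):
            D[i, j] = depths[tips[i]] + depths[tips[j]] - 2 * C[i, j]
    return D
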