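import networkx as nx
import numpy as np
import pytest

from coewc import (
    ExpressionMatrix,
    PPINetwork,
    SyntheticSpec,
    generate,
    make_three_clique_toy,
)


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation under test)
# ---------------------------------------------------------------------------

def brute_clustering(net: PPINetwork, u: str) -> float:
    """CC(u) by exhaustive enumeration of neighbour pairs."""
    nbrs = sorted(net.neighbors(u))
    k = len(nbrs)
    if k < 2:
        return 0.0
    links = sum(
        net.has_edge(nbrs[i], nbrs[j])
        for i in range(k)
        for j in range(i + 1, k)
    )
    return 2.0 * links / (k * (k - 1))


def brute_ecc(net: PPINetwork, u: str, v: str) -> float:
    """ECC(u,v) by direct common-neighbour counting."""
    denom = min(net.degree(u), net.degree(v)) - 1
    if denom <= 0:
        return 0.0
    shared = sum(
        net.has_edge(u, w) and net.has_edge(v, w)
        for w in net.nodes
        if w not in (u, v)
    )
    return shared / denom


def random_net(seed: int, n_max: int = 50) -> PPINetwork:
    """A random G(n, p) network with string protein IDs."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.05, 0.6))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
    relabel = {i: f"P{i:03d}" for i in g.nodes}
    return PPINetwork(
        edges=[(relabel[u], relabel[v]) for u, v in g.edges],
        nodes=relabel.values(),
    )


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def k3() -> PPINetwork:
    return PPINetwork(edges=[("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def k4() -> PPINetwork:
    ids = ["A", "B", "C", "D"]
    return PPINetwork(
        edges=[(ids[i], ids[j]) for i in range(4) for j in range(i + 1, 4)]
    )


@pytest.fixture
def star6() -> PPINetwork:
    return PPINetwork(edges=[("HUB", f"L{i}") for i in range(1, 7)])


@pytest.fixture(scope="session")
def three_clique_toy() -> PPINetwork:
    return make_three_clique_toy()


@pytest.fixture(scope="session")
def default_labeled():
    return generate(SyntheticSpec(seed=0))


@pytest.fixture
def identical_expr():
    """Every protein shares the profile (0,2,0,2): pairwise PCC exactly 1."""

    def make(ids) -> ExpressionMatrix:
        vec = np.array([0.0, 2.0, 0.0, 2.0])
        return ExpressionMatrix(
            n_samples=4, profiles={pid: vec.copy() for pid in ids}
        )

    return make
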