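import itertools

import pytest

import topocomm as tc


@pytest.fixture(scope="session")
def karate():
    """Bundled 34-node / 78-edge karate-club graph and faction truth."""
    return tc.karate_club()


def clique_edges(names):
    return list(itertools.combinations(names, 2))


@pytest.fixture()
def two_cliques_shared_node():
    """Two 4-cliques sharing a single articulation node 'v'."""
    a = ["a1", "a2", "a3"]
    b = ["b1", "b2", "b3"]
    edges = clique_edges(a + ["v"]) + clique_edges(b + ["v"])
    return tc.build_graph(edges)


@pytest.fixture()
def k4_pendant():
    """K4 on a,b,c,d plus a pendant node p attached to a."""
    edges = clique_edges(["a", "b", "c", "d"]) + [("a", "p")]
    return tc.build_graph(edges)


@pytest.fixture()
def three_cluster_weak():
    """Three clusters: one strong-sense, the second balanced so its
    internal edge count equals its external count yet exceeds its
    edges to either single neighbor cluster (weak-sense pattern)."""
    y = clique_edges(["y1", "y2", "y3"])  # 3 internal edges
    a = clique_edges(["a1", "a2", "a3", "a4"])  # strong cluster
    b = clique_edges(["b1", "b2", "b3", "b4"])
    bridges = [("y1", "a1"), ("y2", "a2"), ("y3", "b1")]  # 2 + 1 external
    return tc.build_graph(y + a + b + bridges)


def random_graph(rng, n=30, p=0.2, prefix="n"):
    ids = [f"{prefix}{i:02d}" for i in range(n)]
    edges = [(ids[i], ids[j]) for i in range(n) for j in range(i + 1, n)
             if rng.random() < p]
    return tc.build_graph(edges, nodes=ids)
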