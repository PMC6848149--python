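import networkx as nx
import pytest


@pytest.fixture
def path3() -> nx.Graph:
    """a - b - c"""
    return nx.Graph([("a", "b"), ("b", "c")])


@pytest.fixture
def star5() -> nx.Graph:
    """Star on 5 nodes: center c with 4 leaves."""
    return nx.Graph([("c", f"l{i}") for i in range(4)])


@pytest.fixture
def k4() -> nx.Graph:
    return nx.relabel_nodes(nx.complete_graph(4), {i: f"n{i}" for i in range(4)})


@pytest.fixture
def kite() -> nx.Graph:
    """Triangle a-b-c plus pendant edge c-d."""
    return nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")])


@pytest.fixture
def two_k5_bridge() -> nx.Graph:
    """Two K5 cliques joined by a single edge."""
    G = nx.Graph()
    left = [f"a{i}" for i in range(5)]
    right = [f"b{i}" for i in range(5)]
    for grp in (left, right):
        G.add_edges_from((u, v) for i, u in enumerate(grp) for v in grp[i + 1:])
    G.add_edge(left[0], right[0])
    return G


@pytest.fixture
def two_k3() -> nx.Graph:
    """Two disjoint triangles."""
    return nx.Graph(
        [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")]
    )
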