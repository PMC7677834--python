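import networkx as nx
import pytest

from clusterm.netio import NetworkCollection, PPINetwork, SimilarityMap
from clusterm.separation import Neighborhood


def make_network(edges, tag="net", isolates=()):
    g = nx.Graph()
    g.add_edges_from(edges)
    g.add_nodes_from(isolates)
    return PPINetwork(tag, g)


@pytest.fixture
def path_network():
    """The 5-protein path a-b-c-d-e."""
    return make_network([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")], tag="path")


@pytest.fixture
def bridged_triangles_network():
    """Two triangles {a,b,c} and {d,e,f} joined by the bridge c-d, with one
    pendant protein hanging off each of d, e, f so that the 6-node core is
    not simply a connected component of its host."""
    return make_network(
        [
            ("a", "b"), ("b", "c"), ("a", "c"),
            ("d", "e"), ("e", "f"), ("d", "f"),
            ("c", "d"),
            ("d", "x1"), ("e", "x2"), ("f", "x3"),
        ],
        tag="bridged",
    )


@pytest.fixture
def bridged_triangles_neighborhood(bridged_triangles_network):
    members = ["a", "b", "c", "d", "e", "f"]
    return Neighborhood(
        network=bridged_triangles_network,
        host_network_index=0,
        seed="a",
        members=members,
        scores={p: 1.0 for p in members},
    )


@pytest.fixture
def twin_triangle_world():
    """Two networks, each a single triangle, with perfect one-to-one
    orthology between the triangles."""
    n1 = make_network([("a", "b"), ("b", "c"), ("a", "c")], tag="s1")
    n2 = make_network([("d", "e"), ("e", "f"), ("d", "f")], tag="s2")
    collection = NetworkCollection([n1, n2])
    sim = SimilarityMap()
    for p, q in [("a", "d"), ("b", "e"), ("c", "f")]:
        sim.set(0, p, 1, q, 1.0)
    return collection, sim
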