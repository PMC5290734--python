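import networkx as nx
import pytest

from complexome import InteractionNetwork, SyntheticConfig, generate_layer_family


@pytest.fixture(scope="session")
def atlas_graphs():
    """All 1253 non-isomorphic graphs on up to 7 nodes."""
    from networkx.generators.atlas import graph_atlas_g

    return graph_atlas_g()


@pytest.fixture(scope="session")
def atlas_connected(atlas_graphs):
    """Connected atlas graphs with at least 2 nodes."""
    return [g for g in atlas_graphs
            if g.number_of_nodes() >= 2 and nx.is_connected(g)]


@pytest.fixture(scope="session")
def atlas_small(atlas_graphs):
    """All atlas graphs with at most 6 nodes (for exhaustive sweeps)."""
    return [g for g in atlas_graphs if 1 <= g.number_of_nodes() <= 6]


@pytest.fixture(scope="session")
def default_family():
    """One synthetic family at the reference conditions (seed 0)."""
    return generate_layer_family(SyntheticConfig(seed=0))


@pytest.fixture()
def two_clique_bridge():
    """Two 10-cliques joined by a single bridge edge."""
    g = nx.complete_graph(10)
    h = nx.relabel_nodes(nx.complete_graph(10), {i: i + 10 for i in range(10)})
    g.update(h)
    g.add_edge(0, 10)
    return InteractionNetwork(g, name="two_cliques")


def as_net(g, name=""):
    return InteractionNetwork(nx.Graph(g), name=name)
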