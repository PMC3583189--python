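import networkx as nx
import pytest

from ixprofile.network import PPINetwork
from ixprofile.synthdata import SyntheticConfig, generate_case


def net_from_edges(edges) -> PPINetwork:
    g = nx.Graph()
    g.add_edges_from(edges)
    return PPINetwork(graph=g)


@pytest.fixture
def path5() -> PPINetwork:
    return net_from_edges([("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")])


@pytest.fixture
def triangle() -> PPINetwork:
    return net_from_edges([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def star4() -> PPINetwork:
    """K1,4: hub H with leaves L1..L4."""
    return net_from_edges([("H", f"L{i}") for i in range(1, 5)])


@pytest.fixture
def bridged_cliques() -> PPINetwork:
    """Two 4-cliques joined by a single bridge edge."""
    g = nx.Graph()
    for names in (["A1", "A2", "A3", "A4"], ["B1", "B2", "B3", "B4"]):
        for i in range(4):
            for j in range(i + 1, 4):
                g.add_edge(names[i], names[j])
    g.add_edge("A4", "B1")
    return PPINetwork(graph=g)


@pytest.fixture(scope="session")
def default_case():
    """One synthetic study under the default generator condition."""
    return generate_case(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def small_case():
    """A fast, small synthetic study for CLI / plumbing tests."""
    return SyntheticConfig(seed=7, n_modules=3, module_size=4,
                           n_samples_per_class=5, p_out=0.1)
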