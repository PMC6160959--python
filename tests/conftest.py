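import networkx as nx
import pytest

from pxea.synthetic_data import toy_interactome


@pytest.fixture
def path_graph():
    """Path a-b-c-d."""
    return nx.path_graph(["a", "b", "c", "d"])


@pytest.fixture(scope="session")
def er_graph():
    """Connected Erdős–Rényi graph, 200 nodes, p=0.05."""
    return toy_interactome(200, "erdos_renyi", 0.05, seed=11)


@pytest.fixture(scope="session")
def ba_graph():
    """Connected Barabási–Albert graph, 500 nodes, m=2."""
    return toy_interactome(500, "barabasi_albert", 2, seed=7)


@pytest.fixture(scope="session")
def small_ba_graph():
    """Connected Barabási–Albert graph, 300 nodes, m=2."""
    return toy_interactome(300, "barabasi_albert", 2, seed=13)
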