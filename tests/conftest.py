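import networkx as nx
import numpy as np
import pytest


@pytest.fixture
def triangle():
    G = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
    G.graph["name"] = "triangle"
    return G


@pytest.fixture
def path5():
    return nx.path_graph(["a", "b", "c", "d", "e"])


@pytest.fixture
def small_er():
    G = nx.gnm_random_graph(60, 150, seed=42)
    G.graph["name"] = "er60"
    return G


@pytest.fixture
def small_reference():
    """A modest reference graph for fast expectation tables in tests."""
    G = nx.gnm_random_graph(100, 300, seed=7)
    G.graph["name"] = "ref100"
    return G


@pytest.fixture
def zero_table3():
    """k=3 expectation table with all expectations zero."""
    from netdis import ExpectationTable

    return ExpectationTable(k=3, bin_width=0.01, bins={0: np.zeros(2)})
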