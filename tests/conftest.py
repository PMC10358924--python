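import numpy as np
import pytest

from brainwalk import ElectrodeGraph


def graph_from_edges(labels, edges):
    pos = {lab: i for i, lab in enumerate(labels)}
    a = np.zeros((len(labels), len(labels)), dtype=np.int8)
    for u, v in edges:
        a[pos[u], pos[v]] = a[pos[v], pos[u]] = 1
    return ElectrodeGraph(a, tuple(labels))


def random_graph(n, density, rng, min_edges=1):
    """Random simple graph with at least ``min_edges`` edges."""
    while True:
        a = np.zeros((n, n), dtype=np.int8)
        iu = np.triu_indices(n, k=1)
        a[iu] = rng.random(iu[0].size) < density
        a = a + a.T
        if a.sum() // 2 >= min_edges:
            labels = tuple(f"E{i:02d}" for i in range(n))
            return ElectrodeGraph(a, labels)


@pytest.fixture
def path_abc():
    """3-node path A-B-C."""
    return graph_from_edges(("A", "B", "C"), [("A", "B"), ("B", "C")])


@pytest.fixture
def triangle():
    """Complete graph on 3 nodes."""
    return graph_from_edges(("A", "B", "C"), [("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
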