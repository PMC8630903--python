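import numpy as np
import pytest

from cellblocks import CellGraph


@pytest.fixture
def two_triangles() -> CellGraph:
    return CellGraph(6, np.array([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]))


@pytest.fixture
def two_cliques6() -> CellGraph:
    edges = [(i, j) for i in range(6) for j in range(i + 1, 6)]
    edges += [(i + 6, j + 6) for i in range(6) for j in range(i + 1, 6)]
    return CellGraph(12, np.array(edges))


@pytest.fixture
def small_random_graphs():
    """A reproducible collection of connected-ish random graphs (5-8 nodes)."""
    rng = np.random.default_rng(20240917)
    graphs = []
    while len(graphs) < 8:
        n = int(rng.integers(5, 9))
        edges = [
            (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < 0.45
        ]
        if len(edges) >= 3:
            graphs.append(CellGraph(n, np.array(edges)))
    return graphs
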