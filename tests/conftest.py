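import networkx as nx
import pytest

from grownet.graph_core import ensure_colors


@pytest.fixture
def triangle() -> nx.Graph:
    return ensure_colors(nx.complete_graph(3))


@pytest.fixture
def star4() -> nx.Graph:
    """One hub (node 0) with 4 leaves."""
    return ensure_colors(nx.star_graph(4))


@pytest.fixture
def two_triangles() -> nx.Graph:
    """Two disjoint triangles, each its own module."""
    g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
    for v in g:
        g.nodes[v]["color"] = 0 if v < 3 else 1
    return g


def random_colored_graph(rng, n_max: int = 12, n_colors: int = 3) -> nx.Graph:
    """Small random labeled graph for brute-force oracle comparisons."""
    n = rng.randint(2, n_max)
    g = nx.gnp_random_graph(n, rng.uniform(0.2, 0.8), seed=rng.randint(0, 2**31))
    for v in g:
        g.nodes[v]["color"] = rng.randrange(n_colors)
    return g
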