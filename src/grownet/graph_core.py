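"""Undirected simple colored graphs and the elementary queries on them.

The in-memory container used throughout the package is a
:class:`networkx.Graph` whose nodes carry an integer ``color`` attribute
(the functional-module tag, in ``[0, n_colors)``).  Graphs are simple and
undirected: no self-loops, no multi-edges.  Node ids are opaque integers
that are never reused after deletion, so duplication lineages remain
traceable and runs replay deterministically under a fixed seed.

Degree-0 nodes are first-class citizens: the growth process adds nodes
without edges, so isolated nodes are retained in all distributions and
averages.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

__all__ = [
    "DegreeDistribution",
    "degree_distribution",
    "mean_degree",
    "edge_density",
    "components",
    "giant_component_fraction",
    "ensure_colors",
    "node_colors",
    "num_colors",
    "read_graph",
    "write_graph",
    "read_edgelist_tsv",
    "write_edgelist_tsv",
]


@dataclass
class DegreeDistribution:
    """Degree -> count table for a graph with ``n`` nodes.

    Normalizing the counts by ``n`` gives the degree distribution p(k):
    the probability that a randomly chosen node has k edges.  Counts sum
    to ``n``; the degree-weighted sum equals twice the edge count.
    """

    counts: dict[int, int] = field(default_factory=dict)
    n: int = 0

    def __post_init__(self) -> None:
        self.counts = {int(k): int(c) for k, c in self.counts.items() if c > 0}
        if self.n == 0:
            self.n = sum(self.counts.values())
        if sum(self.counts.values()) != self.n:
            raise ValueError("degree counts must sum to the node count n")

    def p(self, k: int) -> float:
        """Empirical probability of degree ``k``."""
        if self.n == 0:
            raise ValueError("empty distribution")
        return self.counts.get(k, 0) / self.n

    @property
    def mean(self) -> float:
        if self.n == 0:
            raise ValueError("empty distribution")
        return sum(k * c for k, c in self.counts.items()) / self.n

    @property
    def max_degree(self) -> int:
        return max(self.counts) if self.counts else 0

    def degrees(self) -> list[int]:
        """Expand the table back into one degree per node (sorted)."""
        out: list[int] = []
        for k in sorted(self.counts):
            out.extend([k] * self.counts[k])
        return out

    def truncate(self, max_degree: int) -> "DegreeDistribution":
        """Drop nodes of degree > ``max_degree`` (outlier-hub filtering)."""
        kept = {k: c for k, c in self.counts.items() if k <= max_degree}
        return DegreeDistribution(kept, sum(kept.values()))

    @classmethod
    def from_degrees(cls, degrees: list[int]) -> "DegreeDistribution":
        return cls(dict(Counter(int(k) for k in degrees)), len(degrees))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DegreeDistribution":
        """Read a two-column (degree, count) TSV; '#' lines are comments."""
        counts: dict[int, int] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, c = line.split("\t")[:2]
            counts[int(k)] = counts.get(int(k), 0) + int(c)
        return cls(counts, sum(counts.values()))

    def write_tsv(self, path: str | Path) -> None:
        lines = ["# degree\tcount"]
        lines += [f"{k}\t{self.counts[k]}" for k in sorted(self.counts)]
        Path(path).write_text("\n".join(lines) + "\n")


def ensure_colors(g: nx.Graph, n_colors: int | None = None) -> nx.Graph:
    """Assign color 0 to any node missing the attribute.

    An uncolored input graph becomes a one-module graph (every metric can
    then run on unlabeled inputs).  Modifies ``g`` in place and returns it.
    """
    for v, data in g.nodes(data=True):
        if "color" not in data:
            data["color"] = 0
        else:
            data["color"] = int(data["color"])
    if n_colors is not None:
        bad = [v for v, c in g.nodes(data="color") if not 0 <= c < n_colors]
        if bad:
            raise ValueError(f"node colors out of range [0, {n_colors}): {bad[:5]}")
    return g


def node_colors(g: nx.Graph) -> dict[int, int]:
    """Map node-id -> color, defaulting missing attributes to 0."""
    return {v: int(c) if c is not None else 0 for v, c in g.nodes(data="color")}


def num_colors(g: nx.Graph, n_colors: int | None = None) -> int:
    """Number of modules: explicit ``n_colors`` or 1 + max color present."""
    if n_colors is not None:
        return int(n_colors)
    cols = node_colors(g)
    return (max(cols.values()) + 1) if cols else 1


def degree_distribution(g: nx.Graph) -> DegreeDistribution:
    """Degree->count table of ``g``; includes degree-0 nodes."""
    return DegreeDistribution.from_degrees([d for _, d in g.degree()])


def mean_degree(g: nx.Graph) -> float:
    """Mean degree <k> = sum_i k_i / n = 2m/n."""
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    return 2.0 * g.number_of_edges() / n


def edge_density(g: nx.Graph) -> float:
    """Edge density (sparseness) xi = m / (n(n-1)/2).

    The probability that a randomly chosen node pair is connected.
    """
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("edge density needs at least 2 nodes")
    return g.number_of_edges() / (n * (n - 1) / 2)


def components(g: nx.Graph) -> list[set]:
    """Connected components as node-id sets, largest first."""
    return sorted(nx.connected_components(g), key=len, reverse=True)


def giant_component_fraction(g: nx.Graph) -> float:
    """Relative size S of the largest connected component."""
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    return max(len(c) for c in nx.connected_components(g)) / n


# ---------------------------------------------------------------------------
# File formats.  GraphML/GML go through networkx; the edge list is a plain
# two-column TSV (an optional third column is ignored on read).

def write_graph(g: nx.Graph, path: str | Path) -> None:
    path = Path(path)
    ensure_colors(g)
    if path.suffix == ".graphml":
        nx.write_graphml(g, path)
    elif path.suffix == ".gml":
        nx.write_gml(g, path)
    elif path.suffix in (".tsv", ".edgelist", ".txt"):
        write_edgelist_tsv(g, path)
    else:
        raise ValueError(f"unknown graph format: {path.suffix}")


def read_graph(path: str | Path) -> nx.Graph:
    path = Path(path)
    if path.suffix == ".graphml":
        g = nx.read_graphml(path)
        g = nx.relabel_nodes(g, {v: int(v) for v in g.nodes})
    elif path.suffix == ".gml":
        g = nx.read_gml(path, label="id")
    elif path.suffix in (".tsv", ".edgelist", ".txt"):
        g = read_edgelist_tsv(path)
    else:
        raise ValueError(f"unknown graph format: {path.suffix}")
    out = nx.Graph()
    out.add_nodes_from((int(v), dict(d)) for v, d in g.nodes(data=True))
    out.add_edges_from((int(u), int(v)) for u, v in g.edges())
    out.remove_edges_from(nx.selfloop_edges(out))
    return ensure_colors(out)


def write_edgelist_tsv(g: nx.Graph, path: str | Path) -> None:
    lines = ["# node_a\tnode_b"]
    lines += [f"{u}\t{v}" for u, v in sorted(tuple(sorted(e)) for e in g.edges())]
    Path(path).write_text("\n".join(lines) + "\n")


def read_edgelist_tsv(path: str | Path) -> nx.Graph:
    g = nx.Graph()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        u, v = int(parts[0]), int(parts[1])
        if u != v:
            g.add_edge(u, v)
    return g
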