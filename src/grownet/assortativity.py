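"""Generative assortativity matrices and the measured mixing matrix.

The assortativity matrix (e-matrix) plays two roles.  Generatively, its
entry for a color pair gates edge placement during growth: a uniform draw
must fall below the entry for the edge to be accepted.  Entries are used
verbatim as acceptance probabilities, so a uniform rescaling of the matrix
only rescales the overall edge-placement rate — it is the ratios between
entries that fix the mixing structure.  Measured from a labeled graph, the
mixing matrix e_{kl} holds the fraction of edges joining colors k and l,
with each unlike-color edge split half-and-half between the two symmetric
cells so that the matrix is symmetric and sums to 1.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np

from .graph_core import node_colors, num_colors

__all__ = [
    "equal_opportunity",
    "kpartite",
    "lattice_matrix",
    "mixing_matrix",
    "marginals",
    "read_ematrix_tsv",
    "write_ematrix_tsv",
]


def equal_opportunity(n_colors: int, pi: float) -> np.ndarray:
    """The equal-opportunity mixing model.

    A color connects to itself with probability ``pi`` (the intra-module
    edge probability) and to each of the other colors with probability
    (1-pi)/(n_colors-1), irrespective of which.  The 1/n_colors prefactor
    normalizes the matrix so that its entries sum to 1: diagonal entries
    are pi/n_colors, off-diagonal (1-pi)/(n_colors (n_colors-1)), and the
    trace is pi.  pi = 1 is perfectly modular, pi = 0 perfectly
    anti-modular (k-partite).
    """
    if n_colors < 2:
        raise ValueError("equal_opportunity needs at least 2 colors")
    if not 0.0 <= pi <= 1.0:
        raise ValueError("pi must be in [0, 1]")
    off = (1.0 - pi) / (n_colors * (n_colors - 1))
    e = np.full((n_colors, n_colors), off)
    np.fill_diagonal(e, pi / n_colors)
    return e


def kpartite(n_colors: int) -> np.ndarray:
    """Vanishing-diagonal matrix: like colors never connect (k-partite)."""
    return equal_opportunity(n_colors, 0.0)


def lattice_matrix(n_sites: int, neighbor_pairs: list[tuple[int, int]]) -> np.ndarray:
    """Lattice/regular-graph e-matrix: one module per lattice site.

    Entry 1 on each listed neighbor pair (symmetrized), 0 elsewhere.
    Intended use: start from one degree-0 node per module with pn = 0; the
    edge events then enact a percolation problem with edge probability
    q*pe on the geometry dictated by the matrix.
    """
    if n_sites < 2:
        raise ValueError("lattice needs at least 2 sites")
    e = np.zeros((n_sites, n_sites))
    for a, b in neighbor_pairs:
        if not (0 <= a < n_sites and 0 <= b < n_sites) or a == b:
            raise ValueError(f"invalid neighbor pair ({a}, {b})")
        e[a, b] = e[b, a] = 1.0
    return e


def mixing_matrix(g: nx.Graph, n_colors: int | None = None) -> np.ndarray:
    """Measured mixing matrix of a labeled graph.

    e_{kl} is the fraction of edges joining a node of color k to a node of
    color l; unlike-color edges contribute half to each of the two
    symmetric cells, like-color edges wholly to the diagonal.  The entries
    sum to 1 exactly.  Colors in range but absent from the graph keep zero
    rows/columns so the dimension stays predictable.
    """
    m = g.number_of_edges()
    if m == 0:
        raise ValueError("mixing matrix undefined for edgeless graph")
    cols = node_colors(g)
    nc = num_colors(g, n_colors)
    counts = np.zeros((nc, nc))
    for u, v in g.edges():
        cu, cv = cols[u], cols[v]
        if cu == cv:
            counts[cu, cu] += 1.0
        else:
            counts[cu, cv] += 0.5
            counts[cv, cu] += 0.5
    return counts / m


def marginals(e: np.ndarray) -> np.ndarray:
    """a_k = sum_l e_{kl}: fraction of edge ends at color k."""
    return np.asarray(e, dtype=float).sum(axis=1)


def write_ematrix_tsv(e: np.ndarray, path: str | Path) -> None:
    lines = ["\t".join(f"{x:.12g}" for x in row) for row in np.asarray(e, dtype=float)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_ematrix_tsv(path: str | Path) -> np.ndarray:
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append([float(x) for x in line.split("\t")])
    e = np.asarray(rows)
    if e.ndim != 2 or e.shape[0] != e.shape[1]:
        raise ValueError("e-matrix file must be square")
    if not np.allclose(e, e.T, atol=1e-9):
        raise ValueError("e-matrix must be symmetric (tolerance 1e-9)")
    return e
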