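"""Small-world-ness and percolation measurements.

Small-world-ness follows the quantitative measure of Humphries & Gurney:
the mean shortest path L_g and the triangle (transitivity) clustering
coefficient C_g of a graph are each normalized by their means over an
Erdos-Renyi ensemble with the same number of nodes and edges (the G(n,m)
ensemble), giving lambda_g = L_g/L_random and gamma_g = C_g/C_random, and

    S_delta = gamma_g / lambda_g.

A network is non-trivially small-world when S_delta > 1 while the edge
density xi = m/(n(n-1)/2) is low (xi < 0.1): dense networks are trivially
small-world.

For disconnected graphs the mean shortest path is the mean over unordered
reachable pairs within each component, with component means weighted by
component node count; the same convention is applied to the random
baselines for comparability.

The percolation order parameter is the relative size S of the largest
connected component of grown networks; it depends on the growth
parameters only through the ratio q*pe/pn (curves at different absolute
rates collapse), and node fusion shifts the onset of the transition to
smaller ratios because fusing nodes from different clusters merges whole
clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd

from .graph_core import edge_density, giant_component_fraction
from .growth import GrowthParams, grow, spawn_seeds

__all__ = [
    "SmallWorldStats",
    "mean_shortest_path",
    "clustering_triangle",
    "er_baseline",
    "small_world_stats",
    "small_world_sweep",
    "percolation_sweep",
    "ratio_to_probs",
]


@dataclass
class SmallWorldStats:
    """Small-world summary of one graph against its G(n,m) baseline."""

    l_g: float
    c_g: float
    l_random: float
    c_random: float
    xi: float

    @property
    def lambda_g(self) -> float:
        return self.l_g / self.l_random

    @property
    def gamma_g(self) -> float:
        return self.c_g / self.c_random

    @property
    def s_delta(self) -> float:
        return self.gamma_g / self.lambda_g

    @property
    def trivially_small_world(self) -> bool:
        """Dense graphs (xi >= 0.1) are small-world only trivially."""
        return self.xi >= 0.1


def mean_shortest_path(g: nx.Graph) -> float:
    """Mean shortest path over reachable pairs.

    Within each connected component of size >= 2, the mean distance over
    unordered node pairs; the overall value is the component means
    weighted by component node count.  Raises if every node is isolated.
    """
    if g.number_of_nodes() < 2:
        raise ValueError("mean shortest path needs at least 2 nodes")
    total_w = 0.0
    acc = 0.0
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        acc += len(comp) * nx.average_shortest_path_length(sub)
        total_w += len(comp)
    if total_w == 0:
        raise ValueError("no paths: all nodes are isolated")
    return acc / total_w


def clustering_triangle(g: nx.Graph) -> float:
    """Triangle clustering (transitivity): 3 * triangles / connected
    triples.  Distinct from the per-node-average clustering coefficient.
    Returns 0 (with a warning) when the graph has no connected triples."""
    if g.number_of_nodes() < 3:
        raise ValueError("triangle clustering needs at least 3 nodes")
    t = nx.transitivity(g)
    if t == 0 and all(d < 2 for _, d in g.degree()):
        warnings.warn("graph has no connected triples; clustering set to 0", stacklevel=2)
    return t


def er_baseline(
    n: int, m: int, replicates: int = 20, seed: int | None = None
) -> tuple[float, float]:
    """Mean (L_random, C_random) over G(n,m) samples.

    Uniform random graphs with exactly n nodes and m edges, evaluated with
    the same disconnected-graph conventions as the study graph.
    """
    if m > n * (n - 1) // 2:
        raise ValueError("too many edges for a simple graph")
    seeds = spawn_seeds(0 if seed is None else seed, replicates)
    ls, cs = [], []
    for s in seeds:
        er = nx.gnm_random_graph(n, m, seed=s)
        ls.append(mean_shortest_path(er))
        cs.append(nx.transitivity(er))
    return float(np.mean(ls)), float(np.mean(cs))


def small_world_stats(
    g: nx.Graph, replicates: int = 20, seed: int | None = None
) -> SmallWorldStats:
    """Small-world summary of ``g`` vs. its own G(n,m) ensemble."""
    l_r, c_r = er_baseline(g.number_of_nodes(), g.number_of_edges(), replicates, seed)
    return SmallWorldStats(
        l_g=mean_shortest_path(g),
        c_g=clustering_triangle(g),
        l_random=l_r,
        c_random=c_r,
        xi=edge_density(g),
    )


def ratio_to_probs(ratio_pn_pe: float) -> tuple[float, float]:
    """Map a node-to-edge event ratio pn/pe to concrete (pn, pe), keeping
    the larger of the two at 1 so runs stay short; only the ratio matters
    for the grown structure."""
    if ratio_pn_pe <= 0:
        raise ValueError("ratio must be positive")
    if ratio_pn_pe <= 1.0:
        return ratio_pn_pe, 1.0
    return 1.0, 1.0 / ratio_pn_pe


def small_world_sweep(
    ratios,
    n: int = 200,
    q: float = 1.0,
    replicates: int = 100,
    baseline_replicates: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Sweep the ratio pn/pe and measure small-world statistics.

    For each ratio, grows ``replicates`` networks to ``n`` nodes (p = 1,
    pd = 0) and averages L_g, C_g and xi; the G(n,m) baseline for the
    point is evaluated at the round of the mean edge count.  Returns a
    table with lambda_g, gamma_g, s_delta and xi per grid point.
    """
    rows = []
    for i, ratio in enumerate(ratios):
        pn, pe = ratio_to_probs(float(ratio))
        params = GrowthParams(pn=pn, pe=pe, p=1.0, q=q, pd=0.0, max_nodes=n)
        seeds = spawn_seeds(seed + 104729 * i, replicates)
        ls, cs, ms, xis = [], [], [], []
        for s in seeds:
            g = grow(params, seed=s)
            ls.append(mean_shortest_path(g))
            cs.append(nx.transitivity(g))
            ms.append(g.number_of_edges())
            xis.append(edge_density(g))
        m_mean = int(round(float(np.mean(ms))))
        l_r, c_r = er_baseline(n, m_mean, baseline_replicates, seed + 104729 * i + 1)
        l_g, c_g = float(np.mean(ls)), float(np.mean(cs))
        rows.append({
            "ratio_pn_pe": float(ratio),
            "l_g": l_g,
            "c_g": c_g,
            "l_random": l_r,
            "c_random": c_r,
            "lambda_g": l_g / l_r,
            "gamma_g": c_g / c_r if c_r > 0 else np.nan,
            "s_delta": (c_g / c_r) / (l_g / l_r) if c_r > 0 else np.nan,
            "xi": float(np.mean(xis)),
            "xi_se": float(np.std(xis, ddof=1) / np.sqrt(len(xis))),
            "mean_edges": float(np.mean(ms)),
            "replicates": replicates,
        })
    return pd.DataFrame(rows)


def percolation_sweep(
    ratios,
    pn: float = 1.0,
    p: float = 1.0,
    q: float = 1.0,
    pd_prob: float = 0.0,
    r: float = 1.0,
    max_nodes: int | None = 100,
    max_edges: int | None = None,
    replicates: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Giant-component fraction S as a function of the ratio pe/pn.

    For each ratio on the grid, grows ``replicates`` networks with
    pe = ratio * pn (capped at 1 by lowering pn if needed) to the stop
    criterion and averages S.  Curves measured at different absolute pn
    but matched ratios coincide within sampling error; growing with
    fusion (pd_prob > 0, r = 0) moves the onset of the transition to
    smaller ratios.
    """
    rows = []
    for i, ratio in enumerate(ratios):
        ratio = float(ratio)
        pn_i, pe_i = pn, ratio * pn
        if pe_i > 1.0:
            pn_i, pe_i = pn / pe_i, 1.0
        params = GrowthParams(
            pn=pn_i, pe=pe_i, p=p, q=q, pd=pd_prob, r=r,
            max_nodes=max_nodes, max_edges=max_edges,
        )
        seeds = spawn_seeds(seed + 15485863 * i, replicates)
        ss = [giant_component_fraction(grow(params, seed=s)) for s in seeds]
        rows.append({
            "ratio_pe_pn": ratio,
            "pn": pn_i,
            "pe": pe_i,
            "giant_fraction": float(np.mean(ss)),
            "se": float(np.std(ss, ddof=1) / np.sqrt(len(ss))),
            "replicates": replicates,
        })
    return pd.DataFrame(rows)
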