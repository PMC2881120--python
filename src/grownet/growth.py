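"""Stochastic network growth by node, edge, and duplication/fusion events.

Each iteration of the engine fires up to three sub-events sequentially, in
the fixed order node -> edge -> duplication, each independently with its
event probability:

* node event (probability ``pn``): with probability ``p`` a new node is
  added without edges (its color drawn from ``color_probs``), otherwise a
  uniformly random node and all its incident edges are removed;
* edge event (probability ``pe``): with probability ``q`` an edge addition
  is attempted, otherwise a removal.  Addition and removal are conditional:
  a uniformly random node pair is drawn and an edge is only placed if the
  pair is unconnected (removed only if connected).  When an assortativity
  matrix is supplied the addition is additionally gated by the matrix entry
  for the pair's colors and the draw is retried (a fresh pair each time) up
  to ``max_attempts`` times;
* duplication event (probability ``pd``): with probability ``r`` a
  uniformly random ancestor is duplicated — the new node gets the
  ancestor's color and an edge to each of the ancestor's neighbors (but
  not to the ancestor itself) — otherwise two random distinct nodes are
  fused: A inherits all of B's connections and B is deleted (the A-B edge,
  if any, is discarded rather than becoming a self-loop).

Rescaling (p*pn, q*pe, r*pd) by a common factor only changes how many
iterations a network of a given size takes, so only five of the six
probabilities are independent.  The ratio eta = pe/pn is the main control
of the mean degree: for p = q = 1 and no duplication the asymptotic mean
degree is 2*eta, with the exponential (Callaway) degree distribution
p(k) = (2 eta)^k / (1 + 2 eta)^(k+1).

Sub-events that need at least one node (removal, duplication) or at least
two (edge events, fusion) are silently skipped on an undersized graph.
All randomness flows through one seeded generator per run, so a run is
bit-identical under a fixed seed.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .graph_core import ensure_colors

__all__ = [
    "GrowthParams",
    "GrowthTrace",
    "grow",
    "duplicate_node",
    "fuse_nodes",
    "randomize_edges",
    "expected_mean_degree",
    "callaway_pmf",
    "spawn_seeds",
]


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent per-replicate seeds from a master seed.

    Counter-based scheme (numpy SeedSequence), so sweeps can be chunked or
    parallelized without changing results.  Seeds are < 2**31.
    """
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return [int(s) % (2**31) for s in state]


@dataclass
class GrowthParams:
    """The six event probabilities plus module structure and run control.

    pn, pe, pd  -- node / edge / duplication event probabilities
    p, q, r     -- conditional addition probabilities (node add vs remove,
                   edge add vs remove, duplicate vs fuse)
    n_colors    -- number of modules; colors are drawn at node creation
    color_probs -- probability vector over colors (default uniform)
    e_matrix    -- optional n_colors x n_colors assortativity matrix whose
                   entries gate edge placement between color pairs
    max_attempts-- retry budget for gated edge addition (default 1,000)
    max_nodes / max_iterations / max_edges -- stop criterion (>= 1 required)
    iteration_cap -- hard abort guard against parameter settings that can
                   never reach the stop criterion
    seed        -- RNG seed; may be overridden per call to grow()
    """

    pn: float = 0.0
    pe: float = 0.0
    pd: float = 0.0
    p: float = 1.0
    q: float = 1.0
    r: float = 1.0
    n_colors: int = 1
    color_probs: Sequence[float] | None = None
    e_matrix: np.ndarray | None = None
    max_attempts: int = 1000
    max_nodes: int | None = None
    max_iterations: int | None = None
    max_edges: int | None = None
    iteration_cap: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("pn", "pe", "pd", "p", "q", "r"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_colors < 1:
            raise ValueError("n_colors must be >= 1")
        if self.color_probs is not None:
            cp = np.asarray(self.color_probs, dtype=float)
            if cp.shape != (self.n_colors,):
                raise ValueError("color_probs must have length n_colors")
            if (cp < 0).any() or abs(cp.sum() - 1.0) > 1e-9:
                raise ValueError("color_probs must be a probability vector")
            self.color_probs = tuple(cp)
        if self.e_matrix is not None:
            e = np.asarray(self.e_matrix, dtype=float)
            if e.shape != (self.n_colors, self.n_colors):
                raise ValueError("e_matrix dimension must equal n_colors")
            if not np.allclose(e, e.T, atol=1e-9):
                raise ValueError("e_matrix must be symmetric")
            if (e < 0).any() or (e > 1).any():
                raise ValueError("e_matrix entries must be in [0, 1]")
            self.e_matrix = e

    @property
    def eta(self) -> float:
        """Edge-to-node event ratio eta = pe/pn."""
        if self.pn == 0:
            raise ValueError("eta undefined for pn = 0")
        return self.pe / self.pn

    def with_stop(self, **kw) -> "GrowthParams":
        return replace(self, **kw)


@dataclass
class GrowthTrace:
    """Per-iteration event log, for replay checks and debugging."""

    events: list[tuple[int, str]] = field(default_factory=list)

    def append(self, iteration: int, what: str) -> None:
        self.events.append((iteration, what))

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, what in self.events:
            out[what] = out.get(what, 0) + 1
        return out

    def write_tsv(self, path) -> None:
        from pathlib import Path

        lines = ["# iteration\tevent"]
        lines += [f"{i}\t{w}" for i, w in self.events]
        Path(path).write_text("\n".join(lines) + "\n")


class _Engine:
    """Mutable adjacency-set graph with O(1) uniform node sampling.

    Private workhorse behind grow(); converted to networkx at the end.
    """

    __slots__ = ("adj", "color", "nodes", "pos", "next_id", "m", "rng",
                 "params", "cum_colors", "trace")

    def __init__(self, params: GrowthParams, rng: random.Random,
                 trace: GrowthTrace | None = None) -> None:
        self.adj: dict[int, set[int]] = {}
        self.color: dict[int, int] = {}
        self.nodes: list[int] = []
        self.pos: dict[int, int] = {}
        self.next_id = 0
        self.m = 0
        self.rng = rng
        self.params = params
        self.trace = trace
        probs = params.color_probs or [1.0 / params.n_colors] * params.n_colors
        acc, cum = 0.0, []
        for w in probs:
            acc += w
            cum.append(acc)
        cum[-1] = 1.0
        self.cum_colors = cum

    # -- structure manipulation -------------------------------------------

    def seed_from_graph(self, g: nx.Graph) -> None:
        relabel = {}
        for v, data in g.nodes(data=True):
            relabel[v] = self.add_node(int(data.get("color", 0)))
        for u, v in g.edges():
            if u != v:
                self.add_edge(relabel[u], relabel[v])

    def add_node(self, color: int) -> int:
        v = self.next_id
        self.next_id += 1
        self.adj[v] = set()
        self.color[v] = color
        self.pos[v] = len(self.nodes)
        self.nodes.append(v)
        return v

    def remove_node(self, v: int) -> None:
        for u in self.adj[v]:
            self.adj[u].discard(v)
        self.m -= len(self.adj[v])
        del self.adj[v]
        del self.color[v]
        # swap-pop keeps node sampling O(1)
        i, last = self.pos.pop(v), self.nodes[-1]
        if last != v:
            self.nodes[i] = last
            self.pos[last] = i
        self.nodes.pop()

    def add_edge(self, u: int, v: int) -> None:
        self.adj[u].add(v)
        self.adj[v].add(u)
        self.m += 1

    def remove_edge(self, u: int, v: int) -> None:
        self.adj[u].discard(v)
        self.adj[v].discard(u)
        self.m -= 1

    def random_node(self) -> int:
        return self.nodes[self.rng.randrange(len(self.nodes))]

    def random_pair(self) -> tuple[int, int]:
        n = len(self.nodes)
        i = self.rng.randrange(n)
        j = self.rng.randrange(n - 1)
        if j >= i:
            j += 1
        return self.nodes[i], self.nodes[j]

    def draw_color(self) -> int:
        u = self.rng.random()
        for c, acc in enumerate(self.cum_colors):
            if u < acc:
                return c
        return len(self.cum_colors) - 1

    # -- events ------------------------------------------------------------

    def node_event(self, it: int) -> None:
        p = self.params
        if self.rng.random() < p.p:
            self.add_node(self.draw_color())
            self._log(it, "node_add")
        elif self.nodes:
            self.remove_node(self.random_node())
            self._log(it, "node_remove")
        else:
            self._log(it, "node_remove_skipped")

    def edge_event(self, it: int) -> None:
        p = self.params
        if len(self.nodes) < 2:
            self._log(it, "edge_skipped")
            return
        if self.rng.random() < p.q:
            self._log(it, "edge_add" if self._attempt_add_edge() else "edge_add_failed")
        else:
            u, v = self.random_pair()
            if v in self.adj[u]:
                self.remove_edge(u, v)
                self._log(it, "edge_remove")
            else:
                self._log(it, "edge_remove_failed")

    def _attempt_add_edge(self) -> bool:
        p = self.params
        if p.e_matrix is None:
            u, v = self.random_pair()
            if v not in self.adj[u]:
                self.add_edge(u, v)
                return True
            return False
        e = p.e_matrix
        for _ in range(p.max_attempts):
            u, v = self.random_pair()
            if self.rng.random() < e[self.color[u], self.color[v]] and v not in self.adj[u]:
                self.add_edge(u, v)
                return True
        return False

    def duplication_event(self, it: int) -> None:
        p = self.params
        if self.rng.random() < p.r:
            if not self.nodes:
                self._log(it, "duplicate_skipped")
                return
            anc = self.random_node()
            dup = self.add_node(self.color[anc])
            for u in tuple(self.adj[anc]):
                self.add_edge(dup, u)
            self._log(it, "duplicate")
        else:
            if len(self.nodes) < 2:
                self._log(it, "fuse_skipped")
                return
            a, b = self.random_pair()
            gained = self.adj[b] - self.adj[a] - {a}
            self.m += len(gained) - len(self.adj[b])
            for u in self.adj[b]:
                self.adj[u].discard(b)
            for u in gained:
                self.adj[u].add(a)
            self.adj[a] |= gained
            del self.adj[b]
            del self.color[b]
            i, last = self.pos.pop(b), self.nodes[-1]
            if last != b:
                self.nodes[i] = last
                self.pos[last] = i
            self.nodes.pop()
            self._log(it, "fuse")

    def _log(self, it: int, what: str) -> None:
        if self.trace is not None:
            self.trace.append(it, what)

    def step(self, it: int) -> None:
        p = self.params
        if p.pn > 0 and self.rng.random() < p.pn:
            self.node_event(it)
        if p.pe > 0 and self.rng.random() < p.pe:
            self.edge_event(it)
        if p.pd > 0 and self.rng.random() < p.pd:
            self.duplication_event(it)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for v in self.nodes:
            g.add_node(v, color=self.color[v])
        for v in self.nodes:
            for u in self.adj[v]:
                if u > v:
                    g.add_edge(v, u)
        return g


def _stop_reached(eng: _Engine, params: GrowthParams, it: int) -> bool:
    if params.max_nodes is not None and len(eng.nodes) >= params.max_nodes:
        return True
    if params.max_edges is not None and eng.m >= params.max_edges:
        return True
    if params.max_iterations is not None and it >= params.max_iterations:
        return True
    return False


def grow(
    params: GrowthParams,
    initial: nx.Graph | str = "single-seed",
    seed: int | None = None,
    trace: bool = False,
    cap_action: str = "raise",
) -> nx.Graph | tuple[nx.Graph, GrowthTrace]:
    """Run the growth process until the stop criterion is met.

    ``initial`` is ``"single-seed"`` (one node of the first color, the
    usual starting point), ``"one-per-module"`` (one degree-0 node of each
    color), ``"empty"``, or any colored networkx graph.  ``seed`` overrides
    ``params.seed``.  With ``trace=True`` the per-iteration event log is
    returned alongside the graph.

    Raises RuntimeError if the iteration cap is hit before the stop
    criterion (e.g. parameters that only shrink the graph but a target
    node count was requested); with ``cap_action="return"`` the graph
    grown so far is returned instead.
    """
    if params.max_nodes is None and params.max_iterations is None and params.max_edges is None:
        raise ValueError("a stop criterion is required (max_nodes, max_iterations or max_edges)")
    seed = params.seed if seed is None else seed
    rng = random.Random(seed)
    tr = GrowthTrace() if trace else None
    eng = _Engine(params, rng, tr)

    if isinstance(initial, nx.Graph):
        eng.seed_from_graph(initial)
    elif initial == "single-seed":
        eng.add_node(0)
    elif initial == "one-per-module":
        for c in range(params.n_colors):
            eng.add_node(c)
    elif initial != "empty":
        raise ValueError(f"unknown initial condition: {initial!r}")

    cap = params.iteration_cap
    if cap is None:
        if params.max_iterations is not None:
            cap = params.max_iterations
        else:
            # generous default: reaching n nodes needs ~n/(p*pn) iterations
            rate = max(params.p * params.pn, params.r * params.pd, 1e-4)
            target = params.max_nodes if params.max_nodes is not None else params.max_edges
            cap = int(200 * target / rate) + 10_000

    it = 0
    while not _stop_reached(eng, params, it):
        if it >= cap:
            if cap_action == "return":
                break
            raise RuntimeError(
                f"iteration cap {cap} reached before the stop criterion; "
                f"parameters may only shrink the graph (n={len(eng.nodes)}, m={eng.m})"
            )
        eng.step(it)
        it += 1

    g = eng.to_networkx()
    if g.number_of_nodes() == 0:
        import warnings

        warnings.warn("growth run ended with an empty graph", stacklevel=2)
    return (g, tr) if trace else g


def duplicate_node(g: nx.Graph, rng: random.Random | int | None = None) -> nx.Graph:
    """Duplicate one uniformly random node (a copy of a single event).

    The new node receives the ancestor's color and an edge to each of the
    ancestor's neighbors; the ancestor is not its own neighbor, so no
    ancestor-duplicate edge is created (repeated duplication of a single
    node therefore stays edgeless forever).  Returns a new graph; skips
    silently on an empty graph.
    """
    if not isinstance(rng, random.Random):
        rng = random.Random(rng)
    out = ensure_colors(g.copy())
    nodes = sorted(out.nodes)
    if not nodes:
        return out
    anc = nodes[rng.randrange(len(nodes))]
    new = max(nodes) + 1
    out.add_node(new, color=out.nodes[anc]["color"])
    out.add_edges_from((new, u) for u in g.neighbors(anc))
    return out


def fuse_nodes(g: nx.Graph, rng: random.Random | int | None = None) -> nx.Graph:
    """Fuse two uniformly random distinct nodes (one merger event).

    Node A keeps its connections and in addition obtains all of B's, upon
    which B is deleted; a direct A-B edge is discarded (no self-loop) and
    duplicate edges collapse.  The selection is module-independent, so
    fusion can merge whole clusters — the mechanism that shifts the
    percolation onset.  A keeps its color.  Skips silently when n < 2.
    """
    if not isinstance(rng, random.Random):
        rng = random.Random(rng)
    out = ensure_colors(g.copy())
    nodes = sorted(out.nodes)
    if len(nodes) < 2:
        return out
    i = rng.randrange(len(nodes))
    j = rng.randrange(len(nodes) - 1)
    if j >= i:
        j += 1
    a, b = nodes[i], nodes[j]
    out.add_edges_from((a, u) for u in g.neighbors(b) if u != a)
    out.remove_node(b)
    return out


def randomize_edges(g: nx.Graph, updates: int, seed: int | None = None) -> nx.Graph:
    """Edge-randomization control: pn=0, pe=1, q=1/2, pd=0 for ``updates``
    iterations.  Removes and places edges randomly while keeping the node
    count fixed and the edge count fixed in expectation (an unbiased random
    walk in edge-number space)."""
    params = GrowthParams(pn=0.0, pe=1.0, q=0.5, pd=0.0, max_iterations=updates)
    return grow(params, initial=ensure_colors(g.copy()), seed=seed)


def expected_mean_degree(params: GrowthParams, n: int | None = None) -> float:
    """Asymptotic mean degree of the duplication-free process.

    Balancing the per-event node and edge rates (nodes: (2p-1) pn per
    iteration; edges: q pe (1-xi) - (1-q) pe xi - (1-p) pn <k>, with
    sparseness xi ~ <k>/n) gives, at steady state,

        <k> = 2 q eta / (1 + 2 eta / n)  ->  2 q eta   (n -> infinity)

    where eta = pe/pn.  For p = q = 1 this is the stated large-n limit
    <k> = 2 eta of the exponential-growth (Callaway) regime.  Requires
    pn > 0 and is derived for pd = 0.
    """
    if params.pn == 0:
        raise ValueError("no asymptotic degree without node addition (pn = 0)")
    if params.pd != 0:
        raise ValueError("asymptotic mean degree is derived for pd = 0")
    eta = params.eta
    if n is None:
        return 2.0 * params.q * eta
    return 2.0 * params.q * eta / (1.0 + 2.0 * eta / n)


def callaway_pmf(k: int | Iterable[int], eta: float) -> float | np.ndarray:
    """Exponential degree distribution of growth without duplication,

        p(k) = (2 eta)^k / (1 + 2 eta)^(k+1),

    a geometric law with mean <k> = 2 eta (the q = 1, large-n regime)."""
    karr = np.asarray(k)
    with np.errstate(divide="ignore"):
        logp = karr * math.log(2 * eta) - (karr + 1) * math.log1p(2 * eta) \
            if eta > 0 else np.where(karr == 0, 0.0, -np.inf)
    out = np.exp(logp)
    return float(out) if np.isscalar(k) else out
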