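"""Reverse-engineering growth parameters from a degree distribution.

Given a target degree distribution (e.g. measured from a real network),
search the five-dimensional growth-parameter space — pn, p, q, pd, r, with
pe pinned at 1 since only the ratios of the event probabilities matter —
for parameters whose grown networks reproduce the target.

Heavy-tailed degree data is sparse at high degree, so distributions are
compared after *threshold binning*: scanning degrees in ascending order,
a bin is closed as soon as its accumulated count reaches a minimum
occupancy, which stabilizes the tail.  Candidates are scored by the root
mean square difference of binned frequencies on the target's bin grid,
averaged over replicate growth runs, and the search is a Monte-Carlo
hill climb with Gaussian proposals and random restarts.  Agreement
between target and best-fit degree samples is reported with a two-sided
Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .graph_core import DegreeDistribution, degree_distribution
from .growth import GrowthParams, grow, spawn_seeds

__all__ = [
    "BinnedDistribution",
    "FitConfig",
    "FitResult",
    "threshold_bin",
    "bin_on_edges",
    "rms_distance",
    "rank_sum_compare",
    "monte_carlo_fit",
]

FIT_PARAM_NAMES = ("pn", "p", "q", "pd", "r")


@dataclass
class BinnedDistribution:
    """Variable-width binned degree distribution.

    ``edges`` is a list of inclusive (k_min, k_max) ranges, contiguous and
    covering the observed degrees; ``counts`` the node count per bin;
    ``freqs`` the mean frequency count/(n * width).  Every bin except
    possibly the last holds at least ``min_count`` nodes.
    """

    edges: list[tuple[int, int]]
    counts: list[int]
    freqs: list[float]
    n: int
    min_count: int

    def __len__(self) -> int:
        return len(self.edges)


def threshold_bin(d: DegreeDistribution, min_count: int = 10) -> BinnedDistribution:
    """Threshold-bin a degree distribution with variable bin widths.

    Scan occupied degrees in ascending order accumulating counts; close
    the bin as soon as the accumulated count reaches ``min_count``.  The
    last bin absorbs any remainder (it may fall short of the threshold).
    Bin frequency is count / (n * width) with width = k_max - k_min + 1.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if not d.counts:
        raise ValueError("cannot bin an empty distribution")
    ks = sorted(d.counts)
    edges: list[tuple[int, int]] = []
    counts: list[int] = []
    lo, acc = ks[0], 0
    for k in ks:
        acc += d.counts[k]
        if acc >= min_count:
            edges.append((lo, k))
            counts.append(acc)
            lo, acc = k + 1, 0
    if acc > 0:  # last-bin exception: remainder below threshold
        edges.append((lo, ks[-1]))
        counts.append(acc)
    freqs = [c / (d.n * (hi - lo + 1)) for (lo, hi), c in zip(edges, counts)]
    return BinnedDistribution(edges, counts, freqs, d.n, min_count)


def bin_on_edges(d: DegreeDistribution, edges: list[tuple[int, int]]) -> BinnedDistribution:
    """Re-bin a distribution onto a fixed grid (the target's bin edges).

    Degrees below the first bin fold into the first bin, degrees above the
    last fold into the last, so two distributions binned on the same grid
    are always comparable.
    """
    counts = [0] * len(edges)
    for k, c in d.counts.items():
        if k < edges[0][0]:
            counts[0] += c
            continue
        placed = False
        for i, (lo, hi) in enumerate(edges):
            if lo <= k <= hi:
                counts[i] += c
                placed = True
                break
        if not placed:
            counts[-1] += c
    freqs = [c / (d.n * (hi - lo + 1)) for (lo, hi), c in zip(edges, counts)]
    return BinnedDistribution(list(edges), counts, freqs, d.n, 1)


def rms_distance(a: BinnedDistribution, b: BinnedDistribution) -> float:
    """Root mean square difference of per-bin frequencies.

    Both inputs must live on the same bin grid (re-bin with
    :func:`bin_on_edges` first).  Symmetric; zero iff the frequencies are
    identical.
    """
    if a.edges != b.edges:
        raise ValueError("binned distributions are on different grids")
    diff = np.asarray(a.freqs) - np.asarray(b.freqs)
    return float(np.sqrt(np.mean(diff**2)))


def rank_sum_compare(sample_a, sample_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two degree samples.

    Uses the exact null distribution for small untied samples and the
    normal approximation with tie correction otherwise.  A large p-value
    means the test cannot reject that both samples come from the same
    underlying distribution.
    """
    a, b = np.asarray(sample_a), np.asarray(sample_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto",
                             use_continuity=False)
    return float(min(res.pvalue, 1.0))


@dataclass
class FitConfig:
    """Search settings for :func:`monte_carlo_fit`.

    trials       -- candidate evaluations in the exploration stage, split
                    across restarts
    replicates   -- networks grown per exploration evaluation (averaged
                    before scoring)
    sigma        -- Gaussian proposal width, clipped to [0, 1]
    restarts     -- independent hill-climb starts (uniform random initial
                    points; the first restart starts from ``initial`` if
                    given)
    refine_trials, refine_replicates, refine_sigma -- the refinement
                    stage: the best point of every restart is re-scored at
                    ``refine_replicates`` (default 3x replicates, which
                    separates candidate regions whose objectives tie at
                    exploration noise), the winner is climbed for
                    ``refine_trials`` more evaluations with a narrower
                    proposal (default sigma/3)
    min_count    -- threshold-binning occupancy
    fixed        -- parameter values held fixed, e.g. {"p": 1.0}
    initial      -- optional starting point {name: value}
    max_degree   -- optional truncation of both target and candidate
                    distributions (outlier-hub removal)
    """

    trials: int = 200
    replicates: int = 20
    sigma: float = 0.1
    restarts: int = 4
    refine_trials: int | None = None
    refine_replicates: int | None = None
    refine_sigma: float | None = None
    min_count: int = 10
    fixed: dict = field(default_factory=dict)
    initial: dict | None = None
    max_degree: int | None = None


@dataclass
class FitResult:
    params: GrowthParams
    objective: float
    history: list[tuple[int, float]]
    replicates: int
    trials: int
    best_degrees: list[int]

    def as_dict(self) -> dict:
        return {
            "params": {k: getattr(self.params, k) for k in FIT_PARAM_NAMES + ("pe",)},
            "objective": self.objective,
            "trials": self.trials,
            "replicates": self.replicates,
        }


def _mean_binned_freqs(params: GrowthParams, target_n: int, edges, replicates: int,
                       seeds, max_degree: int | None) -> tuple[np.ndarray, list[int]]:
    """Average re-binned frequencies over replicate growth runs."""
    import warnings

    freqs = np.zeros(len(edges))
    pooled: list[int] = []
    for s in seeds[:replicates]:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty graphs are a legal score-0 outcome
            g = grow(params, seed=s, cap_action="return")
        d = degree_distribution(g)
        if max_degree is not None:
            d = d.truncate(max_degree)
        if d.n == 0:
            continue
        freqs += np.asarray(bin_on_edges(d, edges).freqs)
        pooled.extend(d.degrees())
    return freqs / replicates, pooled


def monte_carlo_fit(
    target: DegreeDistribution,
    target_n: int,
    config: FitConfig | None = None,
    seed: int = 0,
) -> FitResult:
    """Search growth parameters whose networks match a target distribution.

    pe is fixed at 1 (the largest probability; only ratios matter) and the
    remaining five parameters (pn, p, q, pd, r) are hill-climbed in
    [0, 1]^5: Gaussian proposals around the incumbent, accepted on
    improvement of the RMS objective, restarted from fresh uniform points.
    Every candidate within a stage is evaluated with the same replicate
    seed set (common random numbers), making the objective a deterministic
    function of the parameters and the climb insensitive to evaluation
    noise.  A second stage re-scores each restart's best point at higher
    replication — distinct parameter regions can tie within the noise of
    the exploration stage — and refines the winner with a narrower
    proposal.

    Growth runs are capped in iterations and edge count; a candidate whose
    parameters cannot reach ``target_n`` nodes within the caps is scored
    on the graph grown so far, which penalizes degenerate regions
    naturally.
    """
    config = config or FitConfig()
    if not target.counts:
        raise ValueError("empty target distribution")
    if config.max_degree is not None:
        target = target.truncate(config.max_degree)
    binned_target = threshold_bin(target, config.min_count)
    edges = binned_target.edges
    tfreq = np.asarray(binned_target.freqs)

    rng = np.random.default_rng(seed)
    # pn floor keeps single evaluations affordable; the iteration and edge
    # caps below bound the pathological corners (pn ~ p ~ 0, or runaway
    # duplication producing graphs far denser than the target).
    lo = np.array([0.01, 0.0, 0.0, 0.0, 0.0])
    hi = np.ones(5)
    cap = 40 * target_n + 5_000
    m_target = sum(k * c for k, c in target.counts.items()) / 2 * (target_n / target.n)
    edge_cap = int(4 * m_target) + 100

    def make_params(x: np.ndarray) -> GrowthParams:
        kw = dict(zip(FIT_PARAM_NAMES, (float(v) for v in x)))
        kw.update(config.fixed)
        return GrowthParams(pe=1.0, max_nodes=target_n, max_edges=edge_cap,
                            iteration_cap=cap, **kw)

    def make_objective(replicates: int, seed_offset: int):
        rep_seeds = spawn_seeds(seed + seed_offset, replicates)

        def objective(x: np.ndarray) -> tuple[float, list[int]]:
            freqs, pooled = _mean_binned_freqs(
                make_params(x), target_n, edges, replicates, rep_seeds,
                config.max_degree)
            return float(np.sqrt(np.mean((freqs - tfreq) ** 2))), pooled

        return objective

    def climb(x, f, pool, objective, n_trials, sigma, trial, history, best):
        for _ in range(n_trials):
            cand = np.clip(x + rng.normal(0.0, sigma, size=5), lo, hi)
            fc, poolc = objective(cand)
            trial += 1
            if fc < f:
                x, f, pool = cand, fc, poolc
            if f < best[1]:
                best[:] = [x.copy(), f, pool]
            history.append((trial, best[1]))
        return x, f, pool, trial

    explore = make_objective(config.replicates, 1)
    history: list[tuple[int, float]] = []
    best = [None, float("inf"), []]  # global incumbent [x, f, pool]
    restart_bests: list[tuple[np.ndarray, float]] = []
    trial = 0
    per_restart = max(1, config.trials // max(1, config.restarts))
    for restart in range(config.restarts):
        if restart == 0 and config.initial:
            x = np.array([config.initial.get(k, 0.5) for k in FIT_PARAM_NAMES])
        else:
            x = rng.uniform(lo, hi)
        x = np.clip(x, lo, hi)
        f, pool = explore(x)
        trial += 1
        if f < best[1]:
            best[:] = [x.copy(), f, pool]
        history.append((trial, best[1]))
        x, f, pool, trial = climb(x, f, pool, explore, per_restart - 1,
                                  config.sigma, trial, history, best)
        restart_bests.append((x.copy(), f))

    # refinement: re-rank restart winners at higher replication, then climb
    refine_reps = config.refine_replicates or 3 * config.replicates
    refine_trials = (config.refine_trials if config.refine_trials is not None
                     else max(1, config.trials // 4))
    refine_sigma = config.refine_sigma or config.sigma / 3
    refine = make_objective(refine_reps, 2)
    best = [None, float("inf"), []]  # re-scored incumbent
    scored = []
    for x, _ in restart_bests:
        f, pool = refine(x)
        trial += 1
        scored.append((f, x, pool))
        if f < best[1]:
            best[:] = [x.copy(), f, pool]
        history.append((trial, best[1]))
    f0, x0, pool0 = min(scored, key=lambda t: t[0])
    _, _, _, trial = climb(x0, f0, pool0, refine, refine_trials,
                           refine_sigma, trial, history, best)

    best_x, best_f, best_pool = best
    if best_x is None or not np.isfinite(best_f):
        raise RuntimeError("search exhausted without a successful growth run")
    return FitResult(
        params=make_params(best_x),
        objective=best_f,
        history=history,
        replicates=refine_reps,
        trials=trial,
        best_degrees=best_pool,
    )
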