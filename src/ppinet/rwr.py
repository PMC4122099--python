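"""Random Walk with Restart (RWR) prioritization of network proteins.

A walker starts on the seed protein(s) and at each step either moves to a
uniformly chosen interaction partner or restarts at the seeds with
probability ``r``:

    p_{t+1} = (1 - r) * W @ p_t + r * p_0

where ``W`` is the column-normalized adjacency matrix and ``p_0`` is uniform
over the seed set.  The steady state ``p_inf`` measures global network
proximity to the seeds; candidate genes are ranked by it, log10-transformed
and classified into letter bins (A = seed, B = scores in (-3, -2],
C = (-4, -3], and so on).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .network_core import PPINetwork, _normalize_symbol

#: restart probability used throughout (Koehler-style prioritization default)
DEFAULT_RESTART = 0.7
#: L1 convergence threshold on successive probability vectors
DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 10_000


@dataclass(frozen=True)
class WalkConfig:
    """Parameters of the restart walk."""

    seeds: frozenset[str]
    r: float = DEFAULT_RESTART
    tol: float = DEFAULT_TOL
    max_iter: int = DEFAULT_MAX_ITER

    def __post_init__(self) -> None:
        if not (0.0 < self.r <= 1.0):
            raise ValueError(f"restart probability must be in (0, 1], got {self.r}")
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")
        if not self.seeds:
            raise ValueError("seed set must be nonempty")
        object.__setattr__(
            self, "seeds", frozenset(_normalize_symbol(s) for s in self.seeds)
        )


class ConvergenceError(RuntimeError):
    """Iteration cap reached before the L1 delta fell below tolerance."""


@dataclass
class TransitionMatrix:
    """Column-normalized adjacency matrix with its node ordering."""

    nodes: list[str]
    matrix: sparse.csr_matrix

    @property
    def index(self) -> dict[str, int]:
        return {node: i for i, node in enumerate(self.nodes)}


@dataclass
class ScoreVector:
    """Steady-state probabilities of the walk, per node."""

    nodes: list[str]
    probabilities: np.ndarray
    seeds: frozenset[str]
    iterations: int
    final_delta: float
    mass_history: list[float] = field(default_factory=list, repr=False)

    def probability(self, symbol: str) -> float:
        return float(self.probabilities[self.nodes.index(_normalize_symbol(symbol))])

    def log10_scores(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log10(self.probabilities)


def build_transition_matrix(net: PPINetwork) -> TransitionMatrix:
    """W[i, j] = 1/degree(j) for i adjacent to j, else 0.

    Every column of a cleaned network sums to exactly 1; a degree-0 node
    would give a zero column and is rejected with a pointer to
    ``clean_network``.
    """
    import networkx as nx

    nodes = sorted(net.graph.nodes)
    degrees = np.array([net.graph.degree(n) for n in nodes], dtype=float)
    if np.any(degrees == 0):
        bad = [n for n, d in zip(nodes, degrees) if d == 0]
        raise ValueError(
            f"degree-0 node(s) {bad[:5]} break column normalization; "
            "run clean_network first"
        )
    adjacency = nx.to_scipy_sparse_array(net.graph, nodelist=nodes, format="csr")
    w = adjacency @ sparse.diags(1.0 / degrees)
    return TransitionMatrix(nodes=nodes, matrix=sparse.csr_matrix(w))


def rwr(w: TransitionMatrix, cfg: WalkConfig) -> ScoreVector:
    """Iterate the restart walk to its steady state.

    ``p_0`` is uniform over the seeds.  Iteration stops once the L1 norm of
    ``p_{t+1} - p_t`` falls below ``cfg.tol``; convergence is geometric with
    ratio at most ``1 - r``.  Probability mass is conserved exactly at every
    step (the history is recorded for auditing).
    """
    index = w.index
    missing = [s for s in cfg.seeds if s not in index]
    if missing:
        raise KeyError(f"seed symbol(s) not in network: {sorted(missing)}")
    n = len(w.nodes)
    p0 = np.zeros(n)
    for seed in cfg.seeds:
        p0[index[seed]] = 1.0 / len(cfg.seeds)
    if cfg.r == 1.0:
        return ScoreVector(
            nodes=list(w.nodes),
            probabilities=p0.copy(),
            seeds=cfg.seeds,
            iterations=0,
            final_delta=0.0,
            mass_history=[1.0],
        )
    p = p0.copy()
    mass_history = [float(p.sum())]
    delta = math.inf
    for iteration in range(1, cfg.max_iter + 1):
        p_next = (1.0 - cfg.r) * (w.matrix @ p) + cfg.r * p0
        delta = float(np.abs(p_next - p).sum())
        p = p_next
        mass_history.append(float(p.sum()))
        if delta < cfg.tol:
            return ScoreVector(
                nodes=list(w.nodes),
                probabilities=p,
                seeds=cfg.seeds,
                iterations=iteration,
                final_delta=delta,
                mass_history=mass_history,
            )
    raise ConvergenceError(
        f"no convergence after {cfg.max_iter} iterations (last L1 delta {delta:.3e})"
    )


def closed_form_rwr(w: TransitionMatrix, cfg: WalkConfig) -> np.ndarray:
    """Direct dense solve of p = r (I - (1-r) W)^{-1} p0.

    Exact steady state of the iteration; intended for small networks and
    cross-validation of the iterative solver.
    """
    index = w.index
    n = len(w.nodes)
    p0 = np.zeros(n)
    for seed in cfg.seeds:
        p0[index[seed]] = 1.0 / len(cfg.seeds)
    dense = w.matrix.toarray()
    return cfg.r * np.linalg.solve(np.eye(n) - (1.0 - cfg.r) * dense, p0)


def bin_letter(score: float, is_seed: bool = False) -> str:
    """Letter bin of a log10 probability score.

    Seeds are ``A``.  Other scores fall into half-open decades
    ``(-k-1, -k]`` lettered from ``B`` at k=2 downward (so -2.5 -> B,
    -3.0 -> C, -3.5 -> C).  Scores above -2 (rare off-seed) clamp to B and
    a ``-inf`` sentinel (zero probability, unreachable component) bins last
    as ``unreachable``.
    """
    if is_seed:
        return "A"
    if math.isinf(score) and score < 0:
        return "unreachable"
    k = max(2, math.floor(-score))
    offset = min(k - 2, ord("Z") - ord("B"))
    return chr(ord("B") + offset)


def score_and_bin(
    scores: ScoreVector, degs: set[str], seeds: frozenset[str] | None = None
) -> pd.DataFrame:
    """Ranked candidate-gene table with log10 scores and letter bins.

    Candidate genes (``degs`` present in the network, seeds excluded) are
    ranked descending by steady-state probability, ties broken
    lexicographically by symbol.  Seeds are appended after the ranked block
    with bin ``A`` and no rank; unreachable genes carry a ``-inf`` score and
    sort last.
    """
    seed_set = seeds if seeds is not None else scores.seeds
    deg_set = {_normalize_symbol(d) for d in degs}
    log_scores = scores.log10_scores()
    by_symbol = dict(zip(scores.nodes, zip(scores.probabilities, log_scores)))

    candidates = sorted((deg_set & set(scores.nodes)) - seed_set)
    ranked = sorted(candidates, key=lambda s: (-by_symbol[s][0], s))
    rows = []
    for rank, symbol in enumerate(ranked, start=1):
        prob, log_score = by_symbol[symbol]
        rows.append(
            {
                "symbol": symbol,
                "probability": float(prob),
                "log10_score": float(log_score),
                "rank": rank,
                "bin": bin_letter(float(log_score)),
            }
        )
    for symbol in sorted(seed_set & set(scores.nodes)):
        prob, log_score = by_symbol[symbol]
        rows.append(
            {
                "symbol": symbol,
                "probability": float(prob),
                "log10_score": float(log_score),
                "rank": pd.NA,
                "bin": "A",
            }
        )
    return pd.DataFrame(
        rows, columns=["symbol", "probability", "log10_score", "rank", "bin"]
    )
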