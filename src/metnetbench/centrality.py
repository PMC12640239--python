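"""Graph centrality measures and inferred-vs-reference comparison.

Four node-level measures summarize network structure:

* degree centrality  deg(i) / (N - 1)
* betweenness        sum over unordered pairs (j, k), j, k != i, of the
  fraction of shortest j-k paths passing through i (unnormalized; unreachable
  pairs contribute 0)
* closeness, harmonic form  (1 / (N - 1)) * sum_j 1 / d_ij  with 1/inf := 0,
  which is well defined on disconnected graphs
* PageRank  the fixed point of
  R_i = alpha * sum_j Adj_ij R_j / deg(j) + (1 - alpha) / N,
  treating each undirected edge as bidirectional; the rank mass of isolated
  (dangling) nodes is redistributed uniformly so the vector keeps summing
  to 1.

Comparison of an inferred network against the reference is summarized per
node by residuals (inferred - reference, positive = overestimate) and
overall by the mean absolute error (MAE).
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

MEASURES = ("degree", "betweenness", "closeness", "pagerank")


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach tolerance; carries the last residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class GraphView:
    """Shortest-path structure of a binary undirected graph.

    ``dist[j, k]`` is the shortest-path length (inf when unreachable) and
    ``sigma[j, k]`` the number of distinct shortest j-k paths (0 when
    unreachable, 1 on the diagonal).
    """

    adjacency: np.ndarray
    dist: np.ndarray
    sigma: np.ndarray

    @classmethod
    def from_adjacency(cls, adjacency: np.ndarray) -> "GraphView":
        a = (np.asarray(adjacency) != 0).astype(np.int8)
        n = a.shape[0]
        dist = np.full((n, n), np.inf)
        sigma = np.zeros((n, n))
        neighbors = [np.flatnonzero(a[i]) for i in range(n)]
        for s in range(n):
            dist[s, s] = 0.0
            sigma[s, s] = 1.0
            queue = deque([s])
            while queue:
                u = queue.popleft()
                for v in neighbors[u]:
                    if np.isinf(dist[s, v]):
                        dist[s, v] = dist[s, u] + 1
                        queue.append(int(v))
                    if dist[s, v] == dist[s, u] + 1:
                        sigma[s, v] += sigma[s, u]
        return cls(adjacency=a, dist=dist, sigma=sigma)


@dataclass(frozen=True)
class CentralityVector:
    measure: str
    names: tuple[str, ...]
    values: np.ndarray
    parameters: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CentralityComparison:
    measure: str
    names: tuple[str, ...]
    residuals: np.ndarray  # inferred - reference; positive = overestimate

    @property
    def mae(self) -> float:
        return float(np.mean(np.abs(self.residuals)))


def degree_centrality(net) -> CentralityVector:
    a = np.asarray(net.values)
    n = a.shape[0]
    if n < 2:
        raise ValueError("degree centrality needs >= 2 nodes")
    return CentralityVector("degree", tuple(net.names), a.sum(axis=0) / (n - 1))


def betweenness(net) -> CentralityVector:
    """Unnormalized betweenness over unordered pairs, endpoints excluded.

    Uses the pair-counting identity: i lies on a shortest j-k path iff
    d(j, i) + d(i, k) = d(j, k), in which case the number of such paths is
    sigma(j, i) * sigma(i, k).
    """
    a = np.asarray(net.values)
    n = a.shape[0]
    if n < 3:
        raise ValueError("betweenness needs >= 3 nodes")
    g = GraphView.from_adjacency(a)
    bc = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if j == i:
                continue
            for k in range(j + 1, n):
                if k == i or np.isinf(g.dist[j, k]):
                    continue
                if g.dist[j, i] + g.dist[i, k] == g.dist[j, k]:
                    bc[i] += g.sigma[j, i] * g.sigma[i, k] / g.sigma[j, k]
    return CentralityVector("betweenness", tuple(net.names), bc)


def closeness(net) -> CentralityVector:
    """Harmonic closeness: mean inverse shortest-path distance to other nodes."""
    a = np.asarray(net.values)
    n = a.shape[0]
    if n < 2:
        raise ValueError("closeness needs >= 2 nodes")
    g = GraphView.from_adjacency(a)
    with np.errstate(divide="ignore"):
        inv = 1.0 / g.dist
    np.fill_diagonal(inv, 0.0)
    inv[np.isinf(g.dist)] = 0.0
    return CentralityVector("closeness", tuple(net.names), inv.sum(axis=1) / (n - 1))


def pagerank(net, alpha: float = 0.85, tol: float = 1e-10, max_iter: int = 1000) -> CentralityVector:
    """PageRank by power iteration on the undirected graph.

    Dangling (isolated) nodes donate their rank mass uniformly to all nodes,
    so the vector sums to 1 at every iteration.  Converges when the L1 change
    between iterations falls below ``tol``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    a = (np.asarray(net.values) != 0).astype(float)
    n = a.shape[0]
    deg = a.sum(axis=1)
    dangling = deg == 0
    inv_deg = np.where(dangling, 0.0, 1.0 / np.maximum(deg, 1.0))
    r = np.full(n, 1.0 / n)
    residual = np.inf
    for _ in range(max_iter):
        contrib = a @ (r * inv_deg)
        dangling_mass = r[dangling].sum()
        r_new = alpha * (contrib + dangling_mass / n) + (1.0 - alpha) / n
        residual = float(np.abs(r_new - r).sum())
        r = r_new
        if residual < tol:
            return CentralityVector("pagerank", tuple(net.names), r, {"alpha": alpha, "tol": tol})
    raise ConvergenceError(f"PageRank did not converge in {max_iter} iterations", residual)


_DISPATCH = {
    "degree": degree_centrality,
    "betweenness": betweenness,
    "closeness": closeness,
    "pagerank": pagerank,
}


def compute(net, measure: str, **kwargs) -> CentralityVector:
    try:
        fn = _DISPATCH[measure]
    except KeyError:
        raise ValueError(f"unknown measure {measure!r}; known: {MEASURES}") from None
    return fn(net, **kwargs)


def centrality_error(pred, ref, measure: str, **kwargs) -> CentralityComparison:
    """Per-node residuals (inferred - reference) and their MAE for one measure."""
    if tuple(pred.names) != tuple(ref.names):
        raise ValueError("name order mismatch between prediction and reference")
    inferred = compute(pred, measure, **kwargs)
    reference = compute(ref, measure, **kwargs)
    return CentralityComparison(measure, tuple(pred.names), inferred.values - reference.values)


def all_errors(pred, ref) -> dict[str, CentralityComparison]:
    return {m: centrality_error(pred, ref, m) for m in MEASURES}


def percentile_ci(values, lo: float = 2.5, hi: float = 97.5) -> tuple[float, float]:
    """95% percentile interval over repetitions (2.5th-97.5th)."""
    arr = np.asarray(values, dtype=float)
    return float(np.percentile(arr, lo)), float(np.percentile(arr, hi))
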