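"""Influence metrics on a connection matrix.

Three per-node measures rank a variable's importance in the fatigue
network: degree (number of incident links), eigen-influence (component of
the dominant eigenvector of the weighted matrix C, the direction the state
dynamics S(t) = C^t S(0) converge to) and betweenness centrality (share of
geodesics passing through the node, computed on the binarised graph).
Network-level influence is summarised by the spectral radius of C, which
also classifies the state dynamics as growing, decaying or marginal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import ConnectionMatrix

__all__ = [
    "NodeMetricsTable",
    "InfluenceState",
    "degree",
    "eigen_analysis",
    "betweenness",
    "betweenness_all",
    "propagate_influence",
    "stability_class",
    "rank_nodes",
    "compute_metrics",
]

_STABILITY_TOL = 1e-9
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class NodeMetricsTable:
    """Per-node influence measures plus the network-level spectrum."""

    per_node: pd.DataFrame  # index: node; columns: degree, eigen_influence, betweenness
    eigenvalues: np.ndarray  # full spectrum of C, ascending
    spectral_radius: float
    stability: str  # growing | decaying | marginal

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self.per_node.index)


@dataclass(frozen=True)
class InfluenceState:
    """Node-state vector after t propagation steps."""

    t: int
    state: np.ndarray


def degree(matrix: ConnectionMatrix, node: str) -> int:
    """Number of links incident to ``node`` (positive off-diagonal entries)."""
    i = matrix.index(node)
    return int(np.count_nonzero(matrix.weights[i] > 0))


def eigen_analysis(
    matrix: ConnectionMatrix,
) -> tuple[np.ndarray, np.ndarray, pd.Series]:
    """Eigendecomposition of C and the per-node eigen-influence scores.

    Returns ``(eigenvalues ascending, dominant eigenvector, eigen_influence)``.
    The dominant eigenvector belongs to the algebraically largest
    eigenvalue, which for a nonnegative symmetric C equals the spectral
    radius (Perron-Frobenius); its sign is fixed so the largest-magnitude
    component is nonnegative. Eigen-influence is the componentwise
    magnitude rescaled to a maximum of one (all zero for an empty graph).
    """
    eigval, eigvec = np.linalg.eigh(matrix.weights)
    dominant = eigvec[:, -1].copy()
    lead = np.argmax(np.abs(dominant))
    if dominant[lead] < 0:
        dominant = -dominant
    influence = np.abs(dominant)
    top = influence.max()
    if matrix.weights.max() <= 0 or top <= 0:
        influence = np.zeros_like(influence)
    else:
        influence = influence / top
    return (
        eigval,
        dominant,
        pd.Series(influence, index=list(matrix.node_names), name="eigen_influence"),
    )


def _geodesics(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """BFS distances and shortest-path counts between all node pairs.

    ``dist[s, v]`` is the unweighted geodesic length (-1 if unreachable)
    and ``sigma[s, v]`` the number of distinct geodesics from s to v.
    """
    k = adj.shape[0]
    neighbors = [np.flatnonzero(adj[i]) for i in range(k)]
    dist = np.full((k, k), -1, dtype=int)
    sigma = np.zeros((k, k), dtype=float)
    for s in range(k):
        dist[s, s] = 0
        sigma[s, s] = 1.0
        frontier = [s]
        d = 0
        while frontier:
            nxt: list[int] = []
            for u in frontier:
                for v in neighbors[u]:
                    if dist[s, v] == -1:
                        dist[s, v] = d + 1
                        nxt.append(v)
                    if dist[s, v] == d + 1:
                        sigma[s, v] += sigma[s, u]
            frontier = nxt
            d += 1
    return dist, sigma


def betweenness_all(
    matrix: ConnectionMatrix, counting: str = "fractional"
) -> pd.Series:
    """Betweenness centrality of every node on the binarised graph.

    For each unordered source-target pair (endpoints excluded), a node on
    at least one geodesic contributes the fraction of geodesics through it
    (``fractional``, the standard Brandes pair-splitting) or the plain
    count of geodesics through it (``integer``). Disconnected pairs
    contribute nothing.
    """
    if counting not in ("fractional", "integer"):
        raise ValueError("counting must be 'fractional' or 'integer'")
    adj = matrix.weights > 0
    k = matrix.k
    dist, sigma = _geodesics(adj)
    scores = np.zeros(k)
    for s in range(k):
        for t in range(s + 1, k):
            if dist[s, t] <= 0:
                continue
            on_path = (
                (dist[s] >= 0)
                & (dist[t] >= 0)
                & (dist[s] + dist[t] == dist[s, t])
            )
            on_path[s] = on_path[t] = False
            through = np.where(on_path, sigma[s] * sigma[t], 0.0)
            if counting == "fractional":
                scores += through / sigma[s, t]
            else:
                scores += through
    return pd.Series(scores, index=list(matrix.node_names), name="betweenness")


def betweenness(
    matrix: ConnectionMatrix, node: str, counting: str = "fractional"
) -> float:
    """Betweenness centrality of a single node (see :func:`betweenness_all`)."""
    matrix.index(node)  # raises for unknown nodes
    return float(betweenness_all(matrix, counting)[node])


def propagate_influence(
    matrix: ConnectionMatrix, s0: np.ndarray, t: int
) -> InfluenceState:
    """State after t steps of the linear dynamics S(t) = C^t S(0)."""
    s = np.asarray(s0, dtype=float)
    if s.shape != (matrix.k,):
        raise ValueError(f"s0 must have length {matrix.k}, got shape {s.shape}")
    if t < 0 or int(t) != t:
        raise ValueError("t must be a nonnegative integer")
    state = s.copy()
    for _ in range(int(t)):
        state = matrix.weights @ state
    return InfluenceState(t=int(t), state=state)


def stability_class(matrix: ConnectionMatrix, tol: float = _STABILITY_TOL) -> str:
    """Classify the dynamics by spectral radius: growing (>1), decaying (<1)."""
    eigval, _, _ = eigen_analysis(matrix)
    radius = float(np.abs(eigval).max())
    if radius > 1 + tol:
        return "growing"
    if radius < 1 - tol:
        return "decaying"
    return "marginal"


def compute_metrics(
    matrix: ConnectionMatrix, counting: str = "fractional"
) -> NodeMetricsTable:
    """All per-node measures and the network-level spectrum in one table."""
    eigval, _, influence = eigen_analysis(matrix)
    deg = pd.Series(
        np.count_nonzero(matrix.weights > 0, axis=1),
        index=list(matrix.node_names),
        name="degree",
    )
    btw = betweenness_all(matrix, counting)
    per_node = pd.concat([deg, influence, btw], axis=1)
    radius = float(np.abs(eigval).max())
    return NodeMetricsTable(
        per_node=per_node,
        eigenvalues=eigval,
        spectral_radius=radius,
        stability=stability_class(matrix),
    )


def rank_nodes(metrics: NodeMetricsTable) -> dict[str, tuple[str, ...]]:
    """Argmax node set per metric; ties are all reported, sorted by name.

    Returns ``{"hub": ..., "max_eigen": ..., "max_betweenness": ...}``.
    """
    if len(metrics.per_node) == 0:
        raise ValueError("empty metrics table")

    def argmax_set(col: str) -> tuple[str, ...]:
        values = metrics.per_node[col]
        top = values.max()
        tol = _TIE_RTOL * max(abs(top), 1.0)
        return tuple(sorted(values.index[values >= top - tol]))

    return {
        "hub": argmax_set("degree"),
        "max_eigen": argmax_set("eigen_influence"),
        "max_betweenness": argmax_set("betweenness"),
    }
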