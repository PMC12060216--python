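"""Weighted-network summaries of connectivity states.

Each state centroid becomes a weighted graph (|correlation| weights by
default) on which two metrics are computed: global efficiency — the mean
inverse weighted shortest-path length over node pairs, with edge length
1/weight and unreachable pairs contributing zero — and the Onnela-style
weighted clustering coefficient (geometric-mean triangle intensity with
weights normalised by the network maximum, nodes of degree < 2
contributing zero).  Both lie in [0, 1] for weights in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path


@dataclass(frozen=True)
class WeightedGraph:
    """Undirected weighted graph: symmetric matrix, zero diagonal, weights in [0,1]."""

    weights: np.ndarray
    nodes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.allclose(W, W.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("diagonal must be zero")
        if np.any((W < 0) | (W > 1)):
            raise ValueError("weights must lie in [0, 1]")
        object.__setattr__(self, "weights", W)
        if not self.nodes:
            object.__setattr__(
                self, "nodes", tuple(f"n{i + 1}" for i in range(W.shape[0]))
            )

    @property
    def n(self) -> int:
        return self.weights.shape[0]


def state_graph(
    centroid: np.ndarray,
    node_labels: list[str] | tuple[str, ...],
    transform: str = "abs",
    threshold: float = 0.0,
) -> WeightedGraph:
    """Build a graph from a state centroid (upper-triangle pair vector).

    ``transform``: ``"abs"`` uses |r|; ``"positive"`` clips negatives to 0;
    ``"threshold"`` keeps |r| above ``threshold`` and zeroes the rest.
    """
    v = np.asarray(centroid, dtype=float)
    n = len(node_labels)
    iu = np.triu_indices(n, k=1)
    if v.size != iu[0].size:
        raise ValueError(f"centroid length {v.size} does not match {n} nodes")
    if transform == "abs":
        w = np.abs(v)
    elif transform == "positive":
        w = np.clip(v, 0.0, None)
    elif transform == "threshold":
        w = np.where(np.abs(v) >= threshold, np.abs(v), 0.0)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    W = np.zeros((n, n))
    W[iu] = w
    W += W.T
    return WeightedGraph(np.clip(W, 0.0, 1.0), tuple(node_labels))


def global_efficiency(g: WeightedGraph) -> float:
    """E = mean over ordered pairs of 1/d_ij, edge length = 1/weight.

    Disconnected pairs contribute 0; the empty graph has efficiency 0.
    """
    n = g.n
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    W = g.weights
    with np.errstate(divide="ignore"):
        lengths = np.where(W > 0, 1.0 / W, np.inf)
    np.fill_diagonal(lengths, 0.0)
    D = shortest_path(lengths, method="D", directed=False)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D[off]) & (D[off] > 0), 1.0 / D[off], 0.0)
    return float(inv.sum() / (n * (n - 1)))


def clustering_coefficient(g: WeightedGraph) -> float:
    """Mean Onnela weighted clustering coefficient.

    Per node: C_i = (1/(k_i(k_i-1))) Σ_{j,h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3} with
    ŵ = w / max(w) and k_i the binary degree; nodes with degree < 2
    contribute 0; averaged over all nodes.
    """
    n = g.n
    if n < 3:
        raise ValueError("clustering coefficient needs at least 3 nodes")
    W = g.weights
    wmax = W.max()
    if wmax == 0:
        return 0.0
    What = (W / wmax) ** (1.0 / 3.0)
    deg = (W > 0).sum(axis=0)
    tri = np.diag(What @ What @ What)  # 2x the per-node triangle intensity sum
    c = np.zeros(n)
    ok = deg >= 2
    c[ok] = tri[ok] / (deg[ok] * (deg[ok] - 1))
    return float(c.mean())


def state_metrics(centroids: np.ndarray, node_labels, transform: str = "abs"):
    """Per-state (efficiency, clustering) for a K x n_pairs centroid matrix."""
    out = []
    for k in range(centroids.shape[0]):
        gr = state_graph(centroids[k], node_labels, transform)
        out.append(
            {
                "state": k,
                "global_efficiency": global_efficiency(gr),
                "clustering_coefficient": clustering_coefficient(gr),
            }
        )
    return out
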