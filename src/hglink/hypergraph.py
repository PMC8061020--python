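"""KNN hypergraph construction and its normalized Laplacian operator.

One hyperedge is generated per training vertex: the vertex itself plus
its k nearest neighbors by Euclidean distance, so every hyperedge has
degree k + 1 and every vertex belongs at least to its own hyperedge.
All hyperedges share the weight 1/|E|.  The smoothness regularizer used
by the learner is the quadratic form of

    Delta = I - Dv^{-1/2} H W De^{-1} H^T Dv^{-1/2},

a positive semi-definite operator: f^T Delta f equals the normalized sum
of squared differences of f across vertices sharing a hyperedge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

__all__ = ["Hypergraph", "NormalizedOperator", "knn_hyperedges", "degrees", "normalized_operator"]


@dataclass
class Hypergraph:
    n_vertices: int
    H: np.ndarray  # |V| x |E| binary incidence
    w: np.ndarray  # positive weight per hyperedge
    Dv: np.ndarray  # vertex degrees d(v) = sum_e w(e) H(v,e)
    De: np.ndarray  # hyperedge degrees delta(e) = sum_v H(v,e)
    k: int


@dataclass
class NormalizedOperator:
    Theta: np.ndarray
    Delta: np.ndarray


def knn_hyperedges(X: np.ndarray, k: int) -> Hypergraph:
    """Build the self-inclusive KNN hypergraph over the rows of X.

    Hyperedge e(v) = {v} U {k nearest neighbors of v}; distance ties are
    broken toward the lower vertex index; w(e) = 1/|E| = 1/n for all e.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 vertices")
    if not 1 <= k <= n - 1:
        raise ValueError(f"k={k} out of range [1, {n - 1}]")
    d2 = squareform(pdist(X, metric="sqeuclidean"))
    H = np.zeros((n, n), dtype=np.int8)
    idx = np.arange(n)
    for v in range(n):
        # stable order: distance, then vertex index; drop v itself
        order = np.lexsort((idx, d2[v]))
        order = order[order != v]
        H[order[:k], v] = 1
        H[v, v] = 1
    w = np.full(n, 1.0 / n)
    dv, de = degrees(H, w)
    return Hypergraph(n, H, w, dv, de, k)


def degrees(H: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vertex degrees d(v) = sum_e w(e) H(v,e) and hyperedge degrees delta(e)."""
    H = np.asarray(H)
    w = np.asarray(w, dtype=float)
    if (w <= 0).any():
        raise ValueError("hyperedge weights must be positive")
    dv = H @ w
    de = H.sum(axis=0).astype(float)
    if (dv <= 0).any():
        v = int(np.argmin(dv))
        raise ValueError(f"vertex {v} has zero degree; cannot normalize")
    return dv, de


def normalized_operator(hg: Hypergraph) -> NormalizedOperator:
    """Theta = Dv^{-1/2} H W De^{-1} H^T Dv^{-1/2} and Delta = I - Theta."""
    if (hg.De <= 0).any():
        raise ValueError("hyperedge with zero degree")
    dv_isqrt = 1.0 / np.sqrt(hg.Dv)
    B = (hg.H * (hg.w / hg.De)) @ hg.H.T  # H W De^{-1} H^T
    Theta = dv_isqrt[:, None] * B * dv_isqrt[None, :]
    Theta = (Theta + Theta.T) / 2.0
    Delta = np.eye(hg.n_vertices) - Theta
    return NormalizedOperator(Theta, Delta)
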