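"""Hypergraph-regularized least-squares projection learning.

The model learns a linear projection P mapping a pair feature vector x
to a relevance score x @ P by minimizing

    tr(P^T X^T Delta X P) + lambda ||X P - Y||_F^2 + mu ||P||_F^2,

where Delta is the normalized hypergraph Laplacian of the KNN hypergraph
built over the training rows of X, lambda weights the empirical loss and
mu is a ridge term guaranteeing a unique solution.  The minimizer is
closed-form:

    P = lambda (X^T Delta X + lambda X^T X + mu I)^{-1} X^T Y.

Labels form a single {0,1} column (l = 1), so scores are scalar and
unbounded; only their ranking matters downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .hypergraph import knn_hyperedges, normalized_operator

__all__ = ["HglConfig", "ProjectionModel", "fit", "solve_projection", "objective", "score"]


@dataclass
class HglConfig:
    """Hyper-parameters: neighbor count k, loss weight lambda, ridge weight mu."""

    k: int = 15
    lam: float = 10.0
    mu: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.lam <= 0 or self.mu <= 0:
            raise ValueError("lambda and mu must be positive")


@dataclass
class ProjectionModel:
    P: np.ndarray
    config: HglConfig
    training_feature_dim: int = field(default=0)

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float).reshape(-1, 1)
        if not np.isfinite(self.P).all():
            raise ValueError("projection matrix has non-finite entries")
        if not self.training_feature_dim:
            self.training_feature_dim = self.P.shape[0]


def solve_projection(
    X: np.ndarray, y: np.ndarray, Delta: np.ndarray, lam: float, mu: float
) -> np.ndarray:
    """Closed-form minimizer of the regularized objective for a given Delta.

    Solves the symmetric positive-definite system
    (X^T Delta X + lam X^T X + mu I) P = lam X^T Y rather than forming an
    explicit inverse.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(y, dtype=float).reshape(-1, 1)
    M = X.T @ Delta @ X + lam * (X.T @ X) + mu * np.eye(X.shape[1])
    rhs = lam * (X.T @ Y)
    return scipy.linalg.solve(M, rhs, assume_a="pos")


def fit(X: np.ndarray, y: np.ndarray, config: HglConfig = HglConfig()) -> ProjectionModel:
    """Fit the projection on training features X and binary labels y.

    Builds the KNN hypergraph over the rows of X, forms Delta, and solves
    the closed-form system.  The hypergraph is a training-time construct
    only; query pairs never join it.
    """
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("training features contain non-finite values")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 training samples")
    if config.k >= n:
        raise ValueError(f"k={config.k} must be < n={n}")
    hg = knn_hyperedges(X, config.k)
    Delta = normalized_operator(hg).Delta
    P = solve_projection(X, y, Delta, config.lam, config.mu)
    return ProjectionModel(P, config, X.shape[1])


def objective(
    P: np.ndarray, X: np.ndarray, y: np.ndarray, Delta: np.ndarray, lam: float, mu: float
) -> float:
    """Value of tr(P^T X^T Delta X P) + lam ||XP - Y||_F^2 + mu ||P||_F^2."""
    P = np.asarray(P, dtype=float).reshape(X.shape[1], -1)
    Y = np.asarray(y, dtype=float).reshape(X.shape[0], -1)
    XP = X @ P
    reg = float(np.trace(XP.T @ Delta @ XP))
    emp = float(np.sum((XP - Y) ** 2))
    ridge = float(np.sum(P**2))
    return reg + lam * emp + mu * ridge


def score(model: ProjectionModel, X_query: np.ndarray) -> np.ndarray:
    """Relevance scores X_query @ P (higher = more likely associated)."""
    X_query = np.atleast_2d(np.asarray(X_query, dtype=float))
    if X_query.shape[1] != model.training_feature_dim:
        raise ValueError(
            f"query feature dimension {X_query.shape[1]} != "
            f"training dimension {model.training_feature_dim}"
        )
    return (X_query @ model.P).ravel()
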