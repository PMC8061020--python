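"""Pair feature assembly and balanced training-set construction.

A miRNA-disease pair (i, j) is represented by the concatenation of row i
of the fused miRNA similarity matrix SM and row j of the fused disease
similarity matrix SD, giving an (nm + nd)-dimensional vector (878 at
HMDD v2.0 scale).  Training uses all known pairs as positives and an
equal-sized seeded uniform sample of unknown pairs as negatives; at
HMDD scale only ~2.9% of all pairs are known positives, so the expected
contamination of the negative sample is small.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import AssociationMatrix, SimilarityMatrix

__all__ = ["PairFeatureSet", "pair_feature", "pair_features", "build_training_set", "enumerate_candidates"]


@dataclass
class PairFeatureSet:
    pairs: list[tuple[int, int]]
    X: np.ndarray
    y: np.ndarray
    rng_seed: object


def pair_feature(SM: SimilarityMatrix, SD: SimilarityMatrix, i: int, j: int) -> np.ndarray:
    """Feature vector of pair (miRNA i, disease j): SM row i ++ SD row j."""
    if not 0 <= i < SM.n:
        raise IndexError(f"miRNA index {i} out of range [0, {SM.n})")
    if not 0 <= j < SD.n:
        raise IndexError(f"disease index {j} out of range [0, {SD.n})")
    return np.concatenate([SM.S[i], SD.S[j]])


def pair_features(SM: SimilarityMatrix, SD: SimilarityMatrix, pairs) -> np.ndarray:
    """Stacked feature matrix for a list of (i, j) pairs."""
    pairs = list(pairs)
    if not pairs:
        return np.empty((0, SM.n + SD.n))
    idx = np.asarray(pairs)
    return np.hstack([SM.S[idx[:, 0]], SD.S[idx[:, 1]]])


def build_training_set(
    A: AssociationMatrix,
    SM: SimilarityMatrix,
    SD: SimilarityMatrix,
    seed,
    exclude_negatives: set[tuple[int, int]] | None = None,
) -> PairFeatureSet:
    """Balanced training set: all positives plus an equal seeded negative sample.

    Negatives are drawn uniformly without replacement from the zero entries
    of A (minus *exclude_negatives*, e.g. held-out positives during cross
    validation).  Positives come first in row-major order, then negatives in
    sampled order.
    """
    if SM.n != A.nm or SD.n != A.nd:
        raise ValueError("similarity matrices do not match association matrix shape")
    pos = [tuple(p) for p in np.argwhere(A.A == 1)]
    pool = [tuple(p) for p in np.argwhere(A.A == 0)]
    if exclude_negatives:
        pool = [p for p in pool if p not in exclude_negatives]
    if len(pool) < len(pos):
        raise ValueError(f"only {len(pool)} unknown pairs available for {len(pos)} negatives")
    rng = np.random.default_rng(seed)
    neg_idx = rng.choice(len(pool), size=len(pos), replace=False)
    neg = [pool[k] for k in neg_idx]
    pairs = pos + neg
    X = pair_features(SM, SD, pairs)
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    return PairFeatureSet(pairs, X, y, seed)


def enumerate_candidates(
    A: AssociationMatrix, exclude: set[tuple[int, int]] | None = None
) -> list[tuple[int, int]]:
    """All unknown pairs (A = 0) minus *exclude*, in row-major order."""
    exclude = exclude or set()
    return [tuple(p) for p in np.argwhere(A.A == 0) if tuple(p) not in exclude]
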