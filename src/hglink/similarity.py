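"""Similarity construction: Gaussian interaction-profile (GIP) kernels,
DAG-based disease semantic similarity, and the zero-fill fusion rule.

The GIP kernel treats each entity's binary association profile BV(i)
(a row of A for miRNAs, a column for diseases) as a point and applies a
Gaussian of the squared Euclidean distance, with the bandwidth gamma set
to the reciprocal of the mean squared profile norm:

    gamma = 1 / ( (1/n) * sum_i ||BV(i)||^2 )
    K(i, j) = exp( -gamma * ||BV(i) - BV(j)||^2 )

Disease semantic similarity scores two diseases by the overlap of their
ancestor DAGs, each term t contributing -log(fraction of disease DAGs
containing t).  Rare (specific) shared ancestors therefore count more
than common (general) ones.  The fused matrices keep the semantic /
functional value where one exists and fall back to the GIP kernel where
the base matrix is zero (sparse MISIM entries, diseases without DAG
overlap), averaging the two elsewhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .data_io import AssociationMatrix, DiseaseOntology, SimilarityMatrix

__all__ = [
    "GipKernelResult",
    "SemanticSimilarityResult",
    "gip_kernel",
    "semantic_value",
    "semantic_similarity",
    "fuse_similarity",
    "fused_matrices",
]


@dataclass
class GipKernelResult:
    K: SimilarityMatrix
    gamma: float


@dataclass
class SemanticSimilarityResult:
    SD_sem: SimilarityMatrix
    DV: dict[str, float]
    contributions: dict[str, dict[str, float]]


def gip_kernel(profiles: np.ndarray, ids: Sequence[str] | None = None) -> GipKernelResult:
    """Gaussian interaction-profile kernel over the rows of *profiles*.

    Parameters
    ----------
    profiles : (n, p) array
        Binary association profiles, one entity per row.
    ids : sequence of str, optional
        Entity identifiers; defaults to stringified row indices.
    """
    P = np.asarray(profiles, dtype=float)
    if P.ndim != 2:
        raise ValueError("profiles must be a 2-D matrix")
    n = P.shape[0]
    mean_sq_norm = float((P**2).sum()) / n
    if mean_sq_norm == 0.0:
        raise ValueError("bandwidth undefined: all association profiles are zero")
    gamma = 1.0 / mean_sq_norm
    d2 = squareform(pdist(P, metric="sqeuclidean")) if n > 1 else np.zeros((1, 1))
    K = np.exp(-gamma * d2)
    np.fill_diagonal(K, 1.0)
    if ids is None:
        ids = [str(i) for i in range(n)]
    return GipKernelResult(SimilarityMatrix(list(ids), K), gamma)


def semantic_value(ontology: DiseaseOntology, disease: str) -> tuple[float, dict[str, float]]:
    """Semantic value DV(d) and per-ancestor contributions for one disease.

    Each term t in the disease's DAG (ancestors plus the disease itself)
    contributes -log(n_t / N) where n_t is the number of disease-of-interest
    DAGs containing t and N the number of diseases of interest.  Natural log.
    """
    if disease not in ontology.disease_ids:
        raise KeyError(f"{disease!r} is not a disease of interest")
    counts = _dag_membership_counts(ontology)
    n_dis = len(ontology.disease_ids)
    contrib = {
        t: -math.log(counts[t] / n_dis) for t in ontology.dag_terms(disease)
    }
    return sum(contrib.values()), contrib


def _dag_membership_counts(ontology: DiseaseOntology) -> dict[str, int]:
    """For each term, the number of disease-of-interest DAGs that include it."""
    counts: dict[str, int] = {}
    for d in ontology.disease_ids:
        for t in ontology.dag_terms(d):
            counts[t] = counts.get(t, 0) + 1
    return counts


def semantic_similarity(
    ontology: DiseaseOntology, disease_ids: Sequence[str] | None = None
) -> SemanticSimilarityResult:
    """Pairwise DAG-overlap semantic similarity over the diseases of interest.

    SD(i, j) = sum over shared DAG terms t of (D_i(t) + D_j(t)) divided by
    DV(i) + DV(j).  A disease whose every DAG term occurs in all DAGs has
    DV = 0; the 0/0 case is resolved to 1 on the diagonal and 0 off it.
    """
    ids = list(disease_ids) if disease_ids is not None else list(ontology.disease_ids)
    unknown = [d for d in ids if d not in set(ontology.disease_ids)]
    if unknown:
        raise KeyError(f"not diseases of interest: {unknown[:5]}")
    counts = _dag_membership_counts(ontology)
    n_dis = len(ontology.disease_ids)
    dag_sets = {d: ontology.dag_terms(d) for d in ids}
    contributions = {
        d: {t: -math.log(counts[t] / n_dis) for t in dag_sets[d]} for d in ids
    }
    DV = {d: sum(contributions[d].values()) for d in ids}
    n = len(ids)
    S = np.zeros((n, n))
    for a in range(n):
        da = ids[a]
        for b in range(a, n):
            db = ids[b]
            denom = DV[da] + DV[db]
            if denom == 0.0:
                val = 1.0 if a == b else 0.0
            else:
                shared = dag_sets[da] & dag_sets[db]
                val = sum(contributions[da][t] + contributions[db][t] for t in shared) / denom
            S[a, b] = S[b, a] = val
    return SemanticSimilarityResult(SimilarityMatrix(ids, S), DV, contributions)


def fuse_similarity(base: SimilarityMatrix, gip: SimilarityMatrix) -> SimilarityMatrix:
    """Fill the base (semantic/functional) matrix's zeros with the GIP kernel.

    Where the base entry is zero the GIP value is used as-is; elsewhere the
    two are averaged.  Both inputs must share identifier order.
    """
    if base.ids != gip.ids:
        raise ValueError("similarity matrices have different identifier order")
    fused = np.where(base.S == 0.0, gip.S, (base.S + gip.S) / 2.0)
    return SimilarityMatrix(list(base.ids), fused)


def fused_matrices(
    am: AssociationMatrix,
    base_sm: SimilarityMatrix,
    sd_sem: SimilarityMatrix,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Fused miRNA (SM) and disease (SD) similarity matrices for a given A.

    Computes the GIP kernels from the rows (miRNAs) and columns (diseases)
    of ``am.A`` and fuses them with the functional base matrix and the
    semantic disease matrix respectively.  Used per CV fold after the
    held-out associations are zeroed.
    """
    if base_sm.ids != am.mirna_ids:
        raise ValueError("functional similarity ids do not match miRNA ids")
    if sd_sem.ids != am.disease_ids:
        raise ValueError("semantic similarity ids do not match disease ids")
    gkm = gip_kernel(am.A, am.mirna_ids).K
    gkd = gip_kernel(am.A.T, am.disease_ids).K
    return fuse_similarity(base_sm, gkm), fuse_similarity(sd_sem, gkd)
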