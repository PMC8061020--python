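"""Cross-validated evaluation of association recovery.

Both schemes hold out known associations, zero them in A, recompute the
GIP kernels and fused similarity matrices from the modified A (the
DAG-based semantic part does not depend on A and is computed once),
retrain on the remaining positives plus a seeded balanced negative
sample, and rank the held-out pairs against all originally-unknown
candidate pairs.

LOOCV holds out one known pair at a time; its global AUC pools each test
pair's normalized rank among its own fold's candidate scores (the
threshold-sweep construction).  k-fold CV partitions the positives into
folds per repeat and reports mean +/- SD of the per-repeat AUCs.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .data_io import AssociationMatrix, DiseaseOntology, SimilarityMatrix
from .features import build_training_set, enumerate_candidates, pair_features
from .hgl_model import HglConfig, fit, score
from .similarity import fused_matrices, semantic_similarity

__all__ = ["CvResult", "roc_auc", "roc_points", "loocv", "kfold_cv", "parameter_sweep"]


@dataclass
class CvResult:
    scheme: str
    per_fold_auc: list[float]
    mean_auc: float
    sd_auc: float
    n_repeats: int
    seeds: list[int]
    extras: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def roc_auc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """AUC = P(pos > neg) + 0.5 P(tie), via the rank threshold sweep."""
    scores_pos = np.asarray(scores_pos, dtype=float)
    scores_neg = np.asarray(scores_neg, dtype=float)
    if scores_pos.size == 0 or scores_neg.size == 0:
        raise ValueError("both score sets must be nonempty")
    y = np.concatenate([np.ones(scores_pos.size), np.zeros(scores_neg.size)])
    s = np.concatenate([scores_pos, scores_neg])
    return float(roc_auc_score(y, s))


def roc_points(scores_pos, scores_neg) -> pd.DataFrame:
    """ROC curve points (threshold, FPR, TPR) from pooled scores."""
    from sklearn.metrics import roc_curve

    y = np.concatenate([np.ones(len(scores_pos)), np.zeros(len(scores_neg))])
    s = np.concatenate([scores_pos, scores_neg])
    fpr, tpr, thr = roc_curve(y, s)
    return pd.DataFrame({"threshold": thr, "FPR": fpr, "TPR": tpr})


def roc_from_ranks(ranks) -> pd.DataFrame:
    """Pooled ROC from per-test normalized ranks among candidate scores.

    Each held-out pair contributes its candidate-quantile r; sweeping the
    rank threshold gives FPR = 1 - r and TPR = fraction of test pairs at
    or above the threshold.
    """
    r = np.sort(np.asarray(ranks, dtype=float))[::-1]
    n = r.size
    tpr = np.concatenate([[0.0], np.arange(1, n + 1) / n, [1.0]])
    fpr = np.concatenate([[0.0], 1.0 - r, [1.0]])
    thr = np.concatenate([[1.0], r, [0.0]])
    return pd.DataFrame({"threshold": thr, "FPR": fpr, "TPR": tpr})


def _semantic_base(ontology: DiseaseOntology, A: AssociationMatrix) -> SimilarityMatrix:
    return semantic_similarity(ontology, A.disease_ids).SD_sem


def _fold_scores(A, A_fold, base_sm, sd_sem, held_out, config, fold_seed, candidates):
    """Retrain with *held_out* zeroed in A_fold; score held-out and candidate pairs."""
    SM, SD = fused_matrices(A_fold, base_sm, sd_sem)
    train = build_training_set(A_fold, SM, SD, fold_seed, exclude_negatives=set(held_out))
    model = fit(train.X, train.y, config)
    test_scores = score(model, pair_features(SM, SD, held_out))
    cand_scores = score(model, pair_features(SM, SD, candidates))
    return test_scores, cand_scores


def loocv(
    A: AssociationMatrix,
    SM_func: SimilarityMatrix,
    ontology: DiseaseOntology,
    config: HglConfig = HglConfig(),
    seed: int = 0,
    max_test_pairs: int | None = None,
) -> CvResult:
    """Leave-one-out CV over known associations.

    Each known pair is zeroed in turn, similarities are recomputed, the
    model is refit, and the pair's score is ranked among all unknown
    candidates.  ``max_test_pairs`` subsamples the held-out pairs (seeded)
    for desk-scale runs; the result then approximates exhaustive LOOCV.
    """
    positives = [tuple(p) for p in np.argwhere(A.A == 1)]
    if len(positives) < 2:
        raise ValueError("need at least 2 known associations")
    candidates = enumerate_candidates(A)
    sd_sem = _semantic_base(ontology, A)
    tested = positives
    if max_test_pairs is not None and max_test_pairs < len(positives):
        rng = np.random.default_rng([seed, 911])
        keep = rng.choice(len(positives), size=max_test_pairs, replace=False)
        tested = [positives[i] for i in sorted(keep)]
    ranks: list[float] = []
    for fold, (i, j) in enumerate(tested):
        A_fold = A.copy()
        A_fold.A[i, j] = 0
        ts, cs = _fold_scores(
            A, A_fold, SM_func, sd_sem, [(i, j)], config, [seed, fold], candidates
        )
        s = ts[0]
        # normalized rank = per-fold P(test > candidate) with ties at half
        ranks.append(((cs < s).sum() + 0.5 * (cs == s).sum()) / len(cs))
    mean = float(np.mean(ranks))
    return CvResult(
        scheme="loocv",
        per_fold_auc=[float(r) for r in ranks],
        mean_auc=mean,
        sd_auc=float(np.std(ranks)),
        n_repeats=1,
        seeds=[seed],
        extras={
            "n_tested": len(tested),
            "subsampled": len(tested) < len(positives),
            "test_ranks": [float(r) for r in ranks],
        },
    )


def kfold_cv(
    A: AssociationMatrix,
    SM_func: SimilarityMatrix,
    ontology: DiseaseOntology,
    config: HglConfig = HglConfig(),
    n_folds: int = 5,
    n_repeats: int = 1,
    seed: int = 0,
) -> CvResult:
    """Repeated k-fold CV over known associations; mean +/- SD over repeats."""
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    positives = [tuple(p) for p in np.argwhere(A.A == 1)]
    if len(positives) < n_folds:
        raise ValueError("fewer positives than folds")
    candidates = enumerate_candidates(A)
    sd_sem = _semantic_base(ontology, A)
    per_fold: list[float] = []
    repeat_means: list[float] = []
    test_ranks: list[float] = []
    for rep in range(n_repeats):
        rng = np.random.default_rng([seed, rep])
        perm = rng.permutation(len(positives))
        folds = np.array_split(perm, n_folds)
        fold_aucs = []
        for f, fold_idx in enumerate(folds):
            if len(fold_idx) == 0:
                raise ValueError("fold with zero positives")
            held = [positives[t] for t in fold_idx]
            A_fold = A.copy()
            for i, j in held:
                A_fold.A[i, j] = 0
            ts, cs = _fold_scores(
                A, A_fold, SM_func, sd_sem, held, config, [seed, rep, f], candidates
            )
            fold_aucs.append(roc_auc(ts, cs))
            for s in ts:
                test_ranks.append(
                    float(((cs < s).sum() + 0.5 * (cs == s).sum()) / len(cs))
                )
        per_fold.extend(fold_aucs)
        repeat_means.append(float(np.mean(fold_aucs)))
    return CvResult(
        scheme="kfold",
        per_fold_auc=[float(a) for a in per_fold],
        mean_auc=float(np.mean(repeat_means)),
        sd_auc=float(np.std(repeat_means)),
        n_repeats=n_repeats,
        seeds=[seed],
        extras={"n_folds": n_folds, "test_ranks": test_ranks},
    )


def parameter_sweep(
    A: AssociationMatrix,
    SM_func: SimilarityMatrix,
    ontology: DiseaseOntology,
    grid: dict,
    scheme: str = "kfold",
    seed: int = 0,
    n_folds: int = 5,
    n_repeats: int = 1,
    max_test_pairs: int | None = None,
) -> pd.DataFrame:
    """Grid sweep over (k, lambda, mu); one CV run per grid point."""
    ks = grid.get("k", [HglConfig.k])
    lams = grid.get("lambda", [HglConfig.lam])
    mus = grid.get("mu", [HglConfig.mu])
    if not (ks and lams and mus):
        raise ValueError("empty parameter grid")
    rows = []
    for k, lam, mu in itertools.product(ks, lams, mus):
        config = HglConfig(k=int(k), lam=float(lam), mu=float(mu))
        if scheme == "kfold":
            res = kfold_cv(A, SM_func, ontology, config, n_folds, n_repeats, seed)
        elif scheme == "loocv":
            res = loocv(A, SM_func, ontology, config, seed, max_test_pairs)
        else:
            raise ValueError(f"unknown scheme {scheme!r} (use 'loocv' or 'kfold')")
        rows.append({"k": k, "lambda": lam, "mu": mu,
                     "mean_auc": res.mean_auc, "sd_auc": res.sd_auc})
    return pd.DataFrame(rows)
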