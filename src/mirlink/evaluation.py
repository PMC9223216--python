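"""Cross-validation protocols and rank-based AUC.

Three protocols: k-fold over known pairs, global leave-one-out over known
pairs, and local (per-disease) leave-one-out.  In every protocol the model
is refit on the masked training matrix — interaction-profile kernels are
recomputed from masked data only, so no test information leaks through the
similarity inputs.  Semantic and functional similarities are
fold-independent inputs and are not masked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .data_model import AssociationDataset, SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = ["CVResult", "auc_rank", "five_fold_cv", "global_loocv", "local_loocv"]

# scorer: training association matrix (nm x nd) -> score matrix (nm x nd)
Scorer = Callable[[np.ndarray], np.ndarray]


@dataclass
class CVResult:
    protocol: str
    aucs: list[float]
    mean_auc: float
    std_auc: float
    roc: tuple[list[float], list[float]] | None
    seed: int | None
    fold_record: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "aucs": self.aucs,
            "mean_auc": self.mean_auc,
            "std_auc": self.std_auc,
            "seed": self.seed,
            "fold_record": self.fold_record,
        }


def auc_rank(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires at least one positive and one negative")
    ranks = rankdata(scores)  # average ranks handle ties at 1/2
    r_pos = float(np.sum(ranks[labels == 1]))
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _summary(protocol: str, aucs: list[float], roc, seed, fold_record) -> CVResult:
    arr = np.asarray(aucs, dtype=float)
    return CVResult(
        protocol=protocol,
        aucs=[float(a) for a in aucs],
        mean_auc=float(arr.mean()),
        std_auc=float(arr.std(ddof=0)),
        roc=roc,
        seed=seed,
        fold_record=fold_record,
    )


def _default_scorer(
    dataset: AssociationDataset,
    sm_functional: SimilarityMatrix | None,
    sd_semantic: SimilarityMatrix | None,
    config,
) -> Scorer:
    from .pipeline import scores_for_training_matrix

    def scorer(A_train: np.ndarray) -> np.ndarray:
        return scores_for_training_matrix(A_train, sm_functional, sd_semantic, config)

    return scorer


def _roc_points(scores: np.ndarray, labels: np.ndarray) -> tuple[list[float], list[float]]:
    fpr, tpr, _ = roc_curve(labels, scores)
    return [float(x) for x in fpr], [float(y) for y in tpr]


def five_fold_cv(
    dataset: AssociationDataset,
    sm_functional: SimilarityMatrix | None,
    sd_semantic: SimilarityMatrix | None,
    config=None,
    repeats: int = 1,
    seed: int = 0,
    scorer: Scorer | None = None,
    n_folds: int = 5,
) -> CVResult:
    """Random k-fold partition of known pairs, repeated ``repeats`` times.

    Per fold, test positives are zeroed in the training matrix, the model is
    refit, and the fold's test positives are pooled against all unknown pairs
    of the full matrix; fold AUCs are averaged into one AUC per repeat.
    """
    A = dataset.A
    positives = np.argwhere(A == 1.0)
    if len(positives) < n_folds:
        raise ValueError(f"need at least {n_folds} known associations")
    if scorer is None:
        scorer = _default_scorer(dataset, sm_functional, sd_semantic, config)
    rng = np.random.default_rng(seed)
    cand_mask = A == 0.0

    aucs: list[float] = []
    fold_record: list[list[list[int]]] = []
    roc = None
    for rep in range(repeats):
        perm = rng.permutation(len(positives))
        folds = np.array_split(perm, n_folds)
        fold_record.append([[int(x) for x in f] for f in folds])
        fold_aucs = []
        pooled_scores: list[np.ndarray] = []
        pooled_labels: list[np.ndarray] = []
        for fold in folds:
            A_train = A.copy()
            test_pairs = positives[fold]
            A_train[test_pairs[:, 0], test_pairs[:, 1]] = 0.0
            S = scorer(A_train)
            pos_scores = S[test_pairs[:, 0], test_pairs[:, 1]]
            neg_scores = S[cand_mask]
            s = np.concatenate([pos_scores, neg_scores])
            lab = np.concatenate([np.ones(len(pos_scores)), np.zeros(len(neg_scores))])
            fold_aucs.append(auc_rank(s, lab))
            if rep == 0:
                pooled_scores.append(s)
                pooled_labels.append(lab)
        aucs.append(float(np.mean(fold_aucs)))
        if rep == 0:
            roc = _roc_points(np.concatenate(pooled_scores), np.concatenate(pooled_labels))
    return _summary(f"{n_folds}cv", aucs, roc, seed, fold_record)


def global_loocv(
    dataset: AssociationDataset,
    sm_functional: SimilarityMatrix | None,
    sd_semantic: SimilarityMatrix | None,
    config=None,
    scorer: Scorer | None = None,
) -> CVResult:
    """Hold out each known pair in turn; rank it against all unknown pairs.

    The overall AUC is the mean over held-out pairs of the fraction of
    candidates scored below the pair (ties at 1/2), which equals the pooled
    Mann-Whitney AUC when each positive is compared with the common
    candidate set from its own refit.
    """
    A = dataset.A
    positives = np.argwhere(A == 1.0)
    if len(positives) < 2:
        raise ValueError("need at least 2 known associations")
    if scorer is None:
        scorer = _default_scorer(dataset, sm_functional, sd_semantic, config)
    cand_mask = A == 0.0

    per_pair: list[float] = []
    pooled_s: list[float] = []
    pooled_l: list[float] = []
    for i, j in positives:
        A_train = A.copy()
        A_train[i, j] = 0.0
        S = scorer(A_train)
        s = np.concatenate([[S[i, j]], S[cand_mask]])
        lab = np.concatenate([[1.0], np.zeros(int(cand_mask.sum()))])
        per_pair.append(auc_rank(s, lab))
        pooled_s.extend([float(S[i, j])] + [float(x) for x in S[cand_mask]])
        pooled_l.extend([1.0] + [0.0] * int(cand_mask.sum()))
    auc = float(np.mean(per_pair))
    roc = _roc_points(np.asarray(pooled_s), np.asarray(pooled_l))
    result = _summary("global-loocv", per_pair, roc, None, [])
    result.mean_auc = auc
    return result


def local_loocv(
    dataset: AssociationDataset,
    sm_functional: SimilarityMatrix | None,
    sd_semantic: SimilarityMatrix | None,
    config=None,
    diseases: Sequence[str] | None = None,
    scorer: Scorer | None = None,
) -> CVResult:
    """Hold out each disease's positives at once; rank them within that disease.

    Diseases with no positives, or with no negatives to rank against, are
    skipped with a warning.  The reported AUC is the per-disease mean.
    """
    A = dataset.A
    if scorer is None:
        scorer = _default_scorer(dataset, sm_functional, sd_semantic, config)
    disease_list = list(diseases) if diseases is not None else list(dataset.disease_ids)

    per_disease: list[float] = []
    evaluated: list[str] = []
    for d in disease_list:
        j = dataset.disease_ids.index(d)
        col = A[:, j]
        n_pos = int(col.sum())
        if n_pos == 0:
            logger.warning("local LOOCV: disease %r has no known miRNAs; skipped", d)
            continue
        if n_pos == len(col):
            logger.warning("local LOOCV: disease %r has no candidate negatives; skipped", d)
            continue
        A_train = A.copy()
        A_train[:, j] = 0.0
        S = scorer(A_train)
        per_disease.append(auc_rank(S[:, j], col.astype(int)))
        evaluated.append(d)
    if not per_disease:
        raise ValueError("no disease could be evaluated")
    return _summary("local-loocv", per_disease, None, None, evaluated)
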