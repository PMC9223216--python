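"""Core containers and I/O for association edge lists, similarity matrices, and scores.

File dialect: UTF-8, tab-separated, lines starting with ``#`` are comments.
Identifier lists are sorted lexicographically at load time so matrix layouts
are deterministic across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationDataset",
    "SimilarityMatrix",
    "ScoreMatrix",
    "load_association_edges",
    "save_association_edges",
    "load_similarity_matrix",
    "save_similarity_matrix",
    "load_scores",
    "save_scores",
    "align",
    "top_k",
]


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} identifiers")
    return ids


@dataclass
class AssociationDataset:
    """Binary miRNA x disease association matrix with ordered identifier lists.

    Row ``i`` of ``A`` is the interaction profile of miRNA ``mirna_ids[i]``;
    column ``j`` is the profile of disease ``disease_ids[j]``.
    """

    mirna_ids: list[str]
    disease_ids: list[str]
    A: np.ndarray

    def __post_init__(self) -> None:
        self.mirna_ids = _check_unique(self.mirna_ids, "miRNA")
        self.disease_ids = _check_unique(self.disease_ids, "disease")
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise ValueError(
                f"association matrix shape {self.A.shape} does not match "
                f"({len(self.mirna_ids)}, {len(self.disease_ids)}) identifiers"
            )
        if self.A.size == 0:
            raise ValueError("empty association matrix")
        if not np.isin(self.A, (0.0, 1.0)).all():
            raise ValueError("association matrix entries must be 0 or 1")

    @property
    def nm(self) -> int:
        return len(self.mirna_ids)

    @property
    def nd(self) -> int:
        return len(self.disease_ids)

    def copy(self) -> "AssociationDataset":
        return AssociationDataset(list(self.mirna_ids), list(self.disease_ids), self.A.copy())


@dataclass
class SimilarityMatrix:
    """Labeled square non-negative similarity matrix for one entity class."""

    ids: list[str]
    S: np.ndarray

    def __post_init__(self) -> None:
        self.ids = _check_unique(self.ids, "similarity")
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.ids)
        if self.S.shape != (n, n):
            raise ValueError(f"similarity matrix shape {self.S.shape} does not match {n} ids")
        if not np.isfinite(self.S).all():
            raise ValueError("similarity matrix contains non-finite entries")
        if (self.S < 0).any():
            raise ValueError("similarity matrix contains negative entries")

    @property
    def n(self) -> int:
        return len(self.ids)

    def symmetrized(self) -> "SimilarityMatrix":
        return SimilarityMatrix(list(self.ids), (self.S + self.S.T) / 2.0)


@dataclass
class ScoreMatrix:
    """Real-valued miRNA x disease score matrix (no binarity constraint)."""

    mirna_ids: list[str]
    disease_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.mirna_ids = _check_unique(self.mirna_ids, "miRNA")
        self.disease_ids = _check_unique(self.disease_ids, "disease")
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise ValueError("score matrix shape does not match identifier lists")
        if not np.isfinite(self.scores).all():
            raise ValueError("score matrix contains non-finite entries")


def _iter_data_lines(path: str | Path):
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def load_association_edges(path: str | Path) -> AssociationDataset:
    """Read a two-column TSV of (miRNA id, disease id) pairs into a binary matrix.

    Duplicate pairs collapse to a single association.  Identifiers are sorted
    lexicographically.  Raises ``ValueError`` naming the line number for any
    line that does not have exactly two columns.
    """
    pairs: set[tuple[str, str]] = set()
    for lineno, line in _iter_data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"{path}: line {lineno}: expected 2 tab-separated columns, got {len(fields)}")
        m, d = fields[0].strip(), fields[1].strip()
        if not m or not d:
            raise ValueError(f"{path}: line {lineno}: empty identifier")
        pairs.add((m, d))
    if not pairs:
        raise ValueError(f"{path}: no association records found")
    mirna_ids = sorted({m for m, _ in pairs})
    disease_ids = sorted({d for _, d in pairs})
    mi = {m: i for i, m in enumerate(mirna_ids)}
    di = {d: j for j, d in enumerate(disease_ids)}
    A = np.zeros((len(mirna_ids), len(disease_ids)))
    for m, d in pairs:
        A[mi[m], di[d]] = 1.0
    return AssociationDataset(mirna_ids, disease_ids, A)


def save_association_edges(dataset: AssociationDataset, path: str | Path) -> None:
    rows, cols = np.nonzero(dataset.A)
    with open(path, "w", encoding="utf-8") as fh:
        for i, j in zip(rows, cols):
            fh.write(f"{dataset.mirna_ids[i]}\t{dataset.disease_ids[j]}\n")


def load_similarity_matrix(path: str | Path) -> SimilarityMatrix:
    """Read a labeled square TSV matrix (header row + label column).

    Row labels must equal column labels in the same order.  The matrix is
    symmetrized as ``(S + S^T)/2``; negative entries are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: matrix is not square: {df.shape}")
    rows = [str(x) for x in df.index]
    cols = [str(x) for x in df.columns]
    if rows != cols:
        raise ValueError(f"{path}: row labels do not match column labels")
    try:
        S = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric entry in similarity matrix") from exc
    if not np.isfinite(S).all():
        raise ValueError(f"{path}: non-finite entry in similarity matrix")
    if (S < 0).any():
        raise ValueError(f"{path}: negative entry in similarity matrix")
    return SimilarityMatrix(rows, (S + S.T) / 2.0)


def save_similarity_matrix(sm: SimilarityMatrix, path: str | Path) -> None:
    pd.DataFrame(sm.S, index=sm.ids, columns=sm.ids).to_csv(path, sep="\t")


def load_scores(path: str | Path) -> ScoreMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return ScoreMatrix([str(x) for x in df.index], [str(x) for x in df.columns], df.to_numpy(dtype=float))


def save_scores(scores: ScoreMatrix, path: str | Path) -> None:
    pd.DataFrame(scores.scores, index=scores.mirna_ids, columns=scores.disease_ids).to_csv(path, sep="\t")


def align(
    dataset: AssociationDataset,
    sm: SimilarityMatrix,
    sd: SimilarityMatrix,
) -> tuple[AssociationDataset, SimilarityMatrix, SimilarityMatrix]:
    """Restrict all three inputs to the intersection of their identifier sets.

    Entities missing from a similarity matrix are dropped from the dataset
    with a logged warning.  Raises on an empty intersection.
    """
    keep_m = sorted(set(dataset.mirna_ids) & set(sm.ids))
    keep_d = sorted(set(dataset.disease_ids) & set(sd.ids))
    if not keep_m or not keep_d:
        raise ValueError("empty identifier intersection between dataset and similarity matrices")
    dropped_m = len(dataset.mirna_ids) - len(keep_m)
    dropped_d = len(dataset.disease_ids) - len(keep_d)
    if dropped_m or dropped_d:
        logger.warning(
            "align: dropping %d miRNAs and %d diseases missing from similarity inputs",
            dropped_m, dropped_d,
        )
    mi = {m: i for i, m in enumerate(dataset.mirna_ids)}
    di = {d: j for j, d in enumerate(dataset.disease_ids)}
    ridx = [mi[m] for m in keep_m]
    cidx = [di[d] for d in keep_d]
    ds = AssociationDataset(keep_m, keep_d, dataset.A[np.ix_(ridx, cidx)])

    smi = {m: i for i, m in enumerate(sm.ids)}
    sdi = {d: j for j, d in enumerate(sd.ids)}
    midx = [smi[m] for m in keep_m]
    didx = [sdi[d] for d in keep_d]
    sm_out = SimilarityMatrix(keep_m, sm.S[np.ix_(midx, midx)])
    sd_out = SimilarityMatrix(keep_d, sd.S[np.ix_(didx, didx)])
    return ds, sm_out, sd_out


def top_k(
    scores: ScoreMatrix,
    disease_id: str,
    k: int,
    exclude_known: bool = False,
    dataset: AssociationDataset | None = None,
) -> list[tuple[str, float]]:
    """Rank miRNAs for one disease by descending score, ties broken lexicographically.

    With ``exclude_known`` (requires ``dataset``), pairs already marked 1 in
    the association matrix are removed before ranking.  The list is truncated
    to at most ``k`` entries; fewer candidates than ``k`` is not an error.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if disease_id not in scores.disease_ids:
        raise KeyError(f"unknown disease id: {disease_id!r}")
    j = scores.disease_ids.index(disease_id)
    candidates = list(range(len(scores.mirna_ids)))
    if exclude_known:
        if dataset is None:
            raise ValueError("exclude_known requires the association dataset")
        dj = dataset.disease_ids.index(disease_id)
        known = {dataset.mirna_ids[i] for i in np.nonzero(dataset.A[:, dj])[0]}
        candidates = [i for i in candidates if scores.mirna_ids[i] not in known]
    ranked = sorted(candidates, key=lambda i: (-scores.scores[i, j], scores.mirna_ids[i]))
    return [(scores.mirna_ids[i], float(scores.scores[i, j])) for i in ranked[:k]]


def save_ranked_list(ranked: list[tuple[str, float]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tmiRNA\tscore\n")
        for r, (m, s) in enumerate(ranked, start=1):
            fh.write(f"{r}\t{m}\t{s:.10g}\n")
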