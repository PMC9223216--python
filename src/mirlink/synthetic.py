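"""Seeded synthetic data with planted low-rank bipartite structure.

The generator plants non-negative latent factors, thresholds their product
to a target density of positives, and corrupts the result with symmetric
flips (lost positives plus spurious positives) — the outliers the denoising
stage is meant to suppress.  Companion similarity inputs are derived from
the same factors: a cosine kernel over miRNA factors, and a disease DAG
corpus whose tree structure follows nearest-neighbor linkage in disease
factor space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics.pairwise import cosine_similarity

from .data_model import AssociationDataset, SimilarityMatrix
from .disease_semantics import DiseaseDAGCorpus

__all__ = ["SyntheticDataset", "generate", "heldout_split"]


@dataclass
class SyntheticDataset:
    dataset: AssociationDataset
    sm_functional: SimilarityMatrix
    dag_corpus: DiseaseDAGCorpus
    U0: np.ndarray
    V0: np.ndarray
    clean_A: np.ndarray
    flipped_off: np.ndarray  # boolean mask of planted positives removed by noise
    flipped_on: np.ndarray   # boolean mask of spurious positives added by noise
    params: dict = field(default_factory=dict)


def _linkage_dag(V0: np.ndarray, disease_ids: list[str]) -> DiseaseDAGCorpus:
    """Forest-shaped corpus: each disease attaches below its nearest
    already-placed disease in latent space, so shared ancestry tracks factor
    proximity.  T(D) is the chain from D up to the root."""
    ndis = len(disease_ids)
    parent: dict[int, int | None] = {0: None}
    for i in range(1, ndis):
        placed = np.array(sorted(parent))
        dists = np.linalg.norm(V0[placed] - V0[i], axis=1)
        parent[i] = int(placed[int(np.argmin(dists))])

    dag: dict[str, dict[str, set[str]]] = {}
    for i, d in enumerate(disease_ids):
        chain = [i]
        while parent[chain[-1]] is not None:
            chain.append(parent[chain[-1]])
        nodes: dict[str, set[str]] = {}
        for a, b in zip(chain, chain[1:]):
            nodes[disease_ids[a]] = {disease_ids[b]}
        nodes[disease_ids[chain[-1]]] = set()
        dag[d] = nodes
    return DiseaseDAGCorpus(list(disease_ids), dag, universe_size=ndis)


def generate(
    nm: int,
    nd: int,
    rank: int,
    density: float,
    noise_rate: float,
    seed: int,
) -> SyntheticDataset:
    """Plant rank-``rank`` structure, threshold to ``density``, flip ``noise_rate``."""
    if rank > min(nm, nd):
        raise ValueError("rank must not exceed min(nm, nd)")
    if not (0.0 < density < 1.0):
        raise ValueError("density must lie in (0, 1)")
    if not (0.0 <= noise_rate < 1.0):
        raise ValueError("noise_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    U0 = np.abs(rng.standard_normal((nm, rank)))
    V0 = np.abs(rng.standard_normal((nd, rank)))
    scores = U0 @ V0.T

    n_pos = int(round(density * nm * nd))
    if n_pos < 1:
        raise ValueError("density too low: zero planted positives")
    order = np.argsort(scores, axis=None)[::-1]
    clean = np.zeros(nm * nd)
    clean[order[:n_pos]] = 1.0
    clean = clean.reshape(nm, nd)

    A = clean.copy()
    flipped_off = np.zeros_like(clean, dtype=bool)
    flipped_on = np.zeros_like(clean, dtype=bool)
    n_flip = int(round(noise_rate * n_pos))
    if n_flip > 0:
        pos_idx = np.flatnonzero(clean.ravel() == 1.0)
        zero_idx = np.flatnonzero(clean.ravel() == 0.0)
        off = rng.choice(pos_idx, size=n_flip, replace=False)
        on = rng.choice(zero_idx, size=n_flip, replace=False)
        A.ravel()[off] = 0.0
        A.ravel()[on] = 1.0
        flipped_off.ravel()[off] = True
        flipped_on.ravel()[on] = True

    width_m = max(4, len(str(nm)))
    width_d = max(4, len(str(nd)))
    mirna_ids = [f"m{i:0{width_m}d}" for i in range(nm)]
    disease_ids = [f"d{j:0{width_d}d}" for j in range(nd)]

    SMf = cosine_similarity(U0)
    np.fill_diagonal(SMf, 1.0)
    sm_functional = SimilarityMatrix(mirna_ids, np.clip((SMf + SMf.T) / 2.0, 0.0, 1.0))

    corpus = _linkage_dag(V0, disease_ids)
    return SyntheticDataset(
        dataset=AssociationDataset(mirna_ids, disease_ids, A),
        sm_functional=sm_functional,
        dag_corpus=corpus,
        U0=U0,
        V0=V0,
        clean_A=clean,
        flipped_off=flipped_off,
        flipped_on=flipped_on,
        params=dict(nm=nm, nd=nd, rank=rank, density=density, noise_rate=noise_rate, seed=seed),
    )


def heldout_split(
    ds: SyntheticDataset, fraction: float, seed: int
) -> tuple[AssociationDataset, list[tuple[str, str]]]:
    """Zero a random ``fraction`` of observed positives; return the train
    dataset and the held-out (miRNA, disease) pairs."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    data = ds.dataset
    pos = np.argwhere(data.A == 1.0)
    n_hold = int(round(fraction * len(pos)))
    if n_hold >= len(pos):
        raise ValueError("fraction would remove every positive")
    chosen = rng.choice(len(pos), size=n_hold, replace=False)
    A_train = data.A.copy()
    held: list[tuple[str, str]] = []
    for idx in chosen:
        i, j = pos[idx]
        A_train[i, j] = 0.0
        held.append((data.mirna_ids[i], data.disease_ids[j]))
    train = AssociationDataset(list(data.mirna_ids), list(data.disease_ids), A_train)
    return train, held
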