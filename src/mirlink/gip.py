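"""Gaussian interaction-profile kernel similarity.

The kernel bandwidth is the raw bandwidth divided by the mean squared
Euclidean norm of the binary profile rows, so the scale adapts to the
average number of known associations per entity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .data_model import AssociationDataset, SimilarityMatrix

__all__ = ["GIPParams", "gip_bandwidth", "gip_kernel", "mirna_gip_kernel", "disease_gip_kernel"]


@dataclass
class GIPParams:
    rho_prime: float = 1.0

    def __post_init__(self) -> None:
        if self.rho_prime <= 0:
            raise ValueError("rho_prime must be positive")


def gip_bandwidth(profiles: np.ndarray, params: GIPParams | None = None) -> float:
    """Normalized bandwidth rho = rho' / mean_i ||row_i||^2."""
    params = params or GIPParams()
    P = np.asarray(profiles, dtype=float)
    mean_sq = float(np.mean(np.sum(P * P, axis=1)))
    if mean_sq <= 0:
        raise ValueError("all-zero profile matrix: bandwidth undefined")
    return params.rho_prime / mean_sq


def gip_kernel(
    profiles: np.ndarray, params: GIPParams | None = None, ids: list[str] | None = None
) -> SimilarityMatrix:
    """S(i,j) = exp(-rho * ||row_i - row_j||^2) over the profile rows."""
    P = np.asarray(profiles, dtype=float)
    rho = gip_bandwidth(P, params)
    if P.shape[0] > 1:
        D2 = squareform(pdist(P, metric="sqeuclidean"))
    else:
        D2 = np.zeros((1, 1))
    S = np.exp(-rho * D2)
    np.fill_diagonal(S, 1.0)
    if ids is None:
        ids = [f"e{i}" for i in range(P.shape[0])]
    return SimilarityMatrix(ids, (S + S.T) / 2.0)


def mirna_gip_kernel(dataset: AssociationDataset, params: GIPParams | None = None) -> SimilarityMatrix:
    """Kernel over miRNAs: profiles are the rows of the association matrix."""
    return gip_kernel(dataset.A, params, ids=list(dataset.mirna_ids))


def disease_gip_kernel(dataset: AssociationDataset, params: GIPParams | None = None) -> SimilarityMatrix:
    """Kernel over diseases: profiles are the columns of the association matrix."""
    return gip_kernel(dataset.A.T, params, ids=list(dataset.disease_ids))
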