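"""Low-rank self-expression denoising of the association matrix.

Solves  min ||Y||_* + phi * ||X||_{2,1}  s.t.  A = A Y + X,  Y = J
by inexact augmented Lagrange multipliers: alternating proximal updates of
J (singular-value thresholding), Y (linear solve against I + A^T A, factored
once), and X (column-wise L2 shrinkage), followed by multiplier and penalty
updates.  The denoised matrix is A Y*.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.linalg import cho_factor, cho_solve

from .data_model import ScoreMatrix

logger = logging.getLogger(__name__)

__all__ = ["LRRParams", "LRRResult", "svt", "l21_shrink", "ialm_lrr", "reconstruct"]


@dataclass
class LRRParams:
    phi: float = 1.0
    alpha0: float = 1e-4
    alpha_max: float = 1e10
    growth: float = 1.1
    eps: float = 1e-8
    max_iters: int = 500

    def __post_init__(self) -> None:
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if self.alpha0 <= 0:
            raise ValueError("alpha0 must be positive")
        if self.growth <= 1:
            raise ValueError("growth must exceed 1")
        if self.eps <= 0:
            raise ValueError("eps must be positive")


@dataclass
class LRRResult:
    Y: np.ndarray
    X: np.ndarray
    J: np.ndarray
    F1: np.ndarray
    F2: np.ndarray
    iterations: int
    r1: float  # ||A - AY - X||_inf at exit
    r2: float  # ||Y - J||_inf at exit
    converged: bool
    residual_history: list[tuple[float, float]] = field(default_factory=list)


def svt(M: np.ndarray, threshold: float) -> np.ndarray:
    """Singular-value thresholding: the proximal operator of the nuclear norm."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    M = np.asarray(M, dtype=float)
    if not np.isfinite(M).all():
        raise ValueError("non-finite input to svt")
    try:
        U, s, Vt = np.linalg.svd(M, full_matrices=False)
    except np.linalg.LinAlgError:
        # gesdd occasionally fails on valid input; gesvd is slower but robust
        U, s, Vt = scipy.linalg.svd(M, full_matrices=False, lapack_driver="gesvd")
    s = np.maximum(s - threshold, 0.0)
    return (U * s) @ Vt


def l21_shrink(M: np.ndarray, threshold: float) -> np.ndarray:
    """Column-wise shrinkage: prox of threshold * sum of column Euclidean norms."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    M = np.asarray(M, dtype=float)
    norms = np.linalg.norm(M, axis=0)
    scale = np.zeros_like(norms)
    nz = norms > threshold
    scale[nz] = (norms[nz] - threshold) / norms[nz]
    return M * scale[np.newaxis, :]


def ialm_lrr(A: np.ndarray, params: LRRParams | None = None) -> LRRResult:
    """Inexact-ALM iteration for the constrained low-rank decomposition.

    Non-convergence within ``max_iters`` returns the last iterate with
    ``converged=False`` and a warning rather than raising.
    """
    params = params or LRRParams()
    A = np.asarray(A, dtype=float)
    if A.size == 0:
        raise ValueError("empty association matrix")
    nm, ndis = A.shape

    AtA = A.T @ A
    # (I + A^T A) is SPD; factor once, reuse every iteration
    chol = cho_factor(np.eye(ndis) + AtA)

    Y = np.zeros((ndis, ndis))
    X = np.zeros((nm, ndis))
    J = np.zeros((ndis, ndis))
    F1 = np.zeros((nm, ndis))
    F2 = np.zeros((ndis, ndis))
    alpha = params.alpha0

    r1 = r2 = np.inf
    history: list[tuple[float, float]] = []
    converged = False
    it = 0
    for it in range(1, params.max_iters + 1):
        J = svt(Y + F2 / alpha, 1.0 / alpha)
        Y = cho_solve(chol, AtA - A.T @ X + J + (A.T @ F1 - F2) / alpha)
        X = l21_shrink(A - A @ Y + F1 / alpha, params.phi / alpha)
        R1 = A - A @ Y - X
        R2 = Y - J
        F1 = F1 + alpha * R1
        F2 = F2 + alpha * R2
        alpha = min(params.growth * alpha, params.alpha_max)
        r1 = float(np.max(np.abs(R1))) if R1.size else 0.0
        r2 = float(np.max(np.abs(R2))) if R2.size else 0.0
        history.append((r1, r2))
        if r1 < params.eps and r2 < params.eps:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"low-rank decomposition did not converge in {params.max_iters} iterations "
            f"(residuals {r1:.3g}, {r2:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    logger.info("ialm_lrr: %d iterations, residuals (%.3g, %.3g), converged=%s", it, r1, r2, converged)
    return LRRResult(Y, X, J, F1, F2, it, r1, r2, converged, history)


def reconstruct(
    A: np.ndarray,
    result: LRRResult,
    mirna_ids: list[str] | None = None,
    disease_ids: list[str] | None = None,
) -> ScoreMatrix:
    """Denoised association scores A* = A Y*."""
    A = np.asarray(A, dtype=float)
    if A.shape[1] != result.Y.shape[0]:
        raise ValueError(f"shape mismatch: A has {A.shape[1]} columns, Y is {result.Y.shape}")
    A_star = A @ result.Y
    if mirna_ids is None:
        mirna_ids = [f"m{i}" for i in range(A.shape[0])]
    if disease_ids is None:
        disease_ids = [f"d{j}" for j in range(A.shape[1])]
    return ScoreMatrix(mirna_ids, disease_ids, A_star)
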