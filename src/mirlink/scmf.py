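"""Similarity-constrained matrix factorization with exact per-row updates.

Minimizes
    1/2 sum_ij (a*_ij - u_i v_j^T)^2
  + theta/2 (sum_i ||u_i||^2 + sum_j ||v_j||^2)
  + sigma/2 sum_ij ||u_i - u_j||^2 SM_ij
  + sigma/2 sum_ij ||v_i - v_j||^2 SD_ij
by Gauss-Seidel sweeps: each latent row is set to the exact minimizer of the
objective with every other row held fixed (a rank x rank linear solve), so
the objective is non-increasing by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .data_model import ScoreMatrix, SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SCMFParams",
    "SCMFModel",
    "scmf_objective",
    "grad_u",
    "grad_v",
    "update_row_u",
    "update_row_v",
    "fit_scmf",
    "predict_scores",
]


@dataclass
class SCMFParams:
    rank: int = 50
    theta: float = 4.0   # L2 weight, best grid value 2^2
    sigma: float = 1.0   # similarity-constraint weight, best grid value 2^0
    max_sweeps: int = 200
    tol: float = 1e-6
    init_mode: Literal["svd", "seeded-random"] = "svd"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.theta < 0 or self.sigma < 0:
            raise ValueError("theta and sigma must be non-negative")
        if self.max_sweeps < 1:
            raise ValueError("max_sweeps must be >= 1")


@dataclass
class SCMFModel:
    U: np.ndarray
    V: np.ndarray
    objective_trace: list[float]
    converged: bool
    sweeps: int
    params: SCMFParams


def _as_array(M) -> np.ndarray:
    if isinstance(M, ScoreMatrix):
        return M.scores
    if isinstance(M, SimilarityMatrix):
        return M.S
    return np.asarray(M, dtype=float)


def scmf_objective(U, V, A_star, SM, SD, params: SCMFParams) -> float:
    A = _as_array(A_star)
    SMm = _as_array(SM)
    SDm = _as_array(SD)
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    if A.shape != (U.shape[0], V.shape[0]) or SMm.shape[0] != U.shape[0] or SDm.shape[0] != V.shape[0]:
        raise ValueError("shape mismatch between factors, scores, and similarity matrices")
    R = A - U @ V.T
    val = 0.5 * float(np.sum(R * R))
    val += 0.5 * params.theta * (float(np.sum(U * U)) + float(np.sum(V * V)))
    if params.sigma > 0:
        # sum_ij ||u_i - u_j||^2 S_ij = sum_i r_i ||u_i||^2 + sum_j c_j ||u_j||^2 - 2 tr(U^T S U)
        for F, S in ((U, SMm), (V, SDm)):
            sq = np.sum(F * F, axis=1)
            pen = float(S.sum(axis=1) @ sq + S.sum(axis=0) @ sq - 2.0 * np.sum(F * (S @ F)))
            val += 0.5 * params.sigma * pen
    return val


def grad_u(i: int, U, V, A_star, SM, params: SCMFParams) -> np.ndarray:
    """Gradient of the objective with respect to latent row u_i."""
    A = _as_array(A_star)
    S = _as_array(SM)
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    srow = S[i, :] + S[:, i]
    g = U[i] @ (V.T @ V) - A[i, :] @ V + params.theta * U[i]
    g += params.sigma * (srow.sum() * U[i] - srow @ U)
    return g


def grad_v(j: int, U, V, A_star, SD, params: SCMFParams) -> np.ndarray:
    """Gradient of the objective with respect to latent row v_j."""
    A = _as_array(A_star)
    S = _as_array(SD)
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    scol = S[:, j] + S[j, :]
    g = V[j] @ (U.T @ U) - A[:, j] @ U + params.theta * V[j]
    g += params.sigma * (scol.sum() * V[j] - scol @ V)
    return g


def _solve_row(rhs: np.ndarray, base: np.ndarray, diag_add: float, label: str) -> np.ndarray:
    H = base + diag_add * np.eye(base.shape[0])
    try:
        return np.linalg.solve(H, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular system while updating {label}") from exc


def update_row_u(i: int, U, V, A_star, SM, params: SCMFParams, VtV: np.ndarray | None = None) -> np.ndarray:
    """Exact minimizer of the objective over u_i with all other rows fixed.

    The self-similarity terms S_ii cancel between the system diagonal and the
    weighted row sum (||u_i - u_i||^2 vanishes), so they are excluded from
    both sides; the result solves the stationarity condition exactly.
    """
    A = _as_array(A_star)
    S = _as_array(SM)
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    if VtV is None:
        VtV = V.T @ V
    srow = S[i, :] + S[:, i]
    s_tot = float(srow.sum() - srow[i])
    rhs = A[i, :] @ V + params.sigma * (srow @ U - srow[i] * U[i])
    return _solve_row(rhs, VtV, params.theta + params.sigma * s_tot, f"u[{i}]")


def update_row_v(j: int, U, V, A_star, SD, params: SCMFParams, UtU: np.ndarray | None = None) -> np.ndarray:
    """Exact minimizer of the objective over v_j with all other rows fixed."""
    A = _as_array(A_star)
    S = _as_array(SD)
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    if UtU is None:
        UtU = U.T @ U
    scol = S[:, j] + S[j, :]
    s_tot = float(scol.sum() - scol[j])
    rhs = A[:, j] @ U + params.sigma * (scol @ V - scol[j] * V[j])
    return _solve_row(rhs, UtU, params.theta + params.sigma * s_tot, f"v[{j}]")


def _init_factors(A: np.ndarray, params: SCMFParams) -> tuple[np.ndarray, np.ndarray]:
    nm, ndis = A.shape
    r = params.rank
    if r > min(nm, ndis):
        raise ValueError(f"rank {r} exceeds min matrix dimension {min(nm, ndis)}")
    if params.init_mode == "svd":
        Uf, s, Vt = np.linalg.svd(A, full_matrices=False)
        root = np.sqrt(s[:r])
        return Uf[:, :r] * root, Vt[:r, :].T * root
    if params.init_mode == "seeded-random":
        rng = np.random.default_rng(params.seed)
        return rng.uniform(size=(nm, r)) * 0.01, rng.uniform(size=(ndis, r)) * 0.01
    raise ValueError(f"unknown init_mode {params.init_mode!r}")


def fit_scmf(A_star, SM, SD, params: SCMFParams) -> SCMFModel:
    """Alternate Gauss-Seidel sweeps over all u rows then all v rows.

    Stops when the relative objective change falls below ``tol`` or after
    ``max_sweeps``; the recorded objective trace is non-increasing.
    """
    A = _as_array(A_star)
    SMm = _as_array(SM)
    SDm = _as_array(SD)
    nm, ndis = A.shape
    if SMm.shape != (nm, nm) or SDm.shape != (ndis, ndis):
        raise ValueError("similarity matrices do not match the score-matrix dimensions")
    U, V = _init_factors(A, params)

    obj = scmf_objective(U, V, A, SMm, SDm, params)
    trace = [obj]
    converged = False
    sweep = 0
    for sweep in range(1, params.max_sweeps + 1):
        VtV = V.T @ V
        for i in range(nm):
            U[i] = update_row_u(i, U, V, A, SMm, params, VtV=VtV)
        UtU = U.T @ U
        for j in range(ndis):
            V[j] = update_row_v(j, U, V, A, SDm, params, UtU=UtU)
        new_obj = scmf_objective(U, V, A, SMm, SDm, params)
        trace.append(new_obj)
        if abs(obj - new_obj) / max(abs(obj), 1.0) < params.tol:
            converged = True
            obj = new_obj
            break
        obj = new_obj
    logger.info("fit_scmf: %d sweeps, objective %.6g, converged=%s", sweep, obj, converged)
    return SCMFModel(U, V, trace, converged, sweep, params)


def predict_scores(
    model: SCMFModel,
    mirna_ids: list[str] | None = None,
    disease_ids: list[str] | None = None,
) -> ScoreMatrix:
    """Predicted association scores U V^T."""
    P = model.U @ model.V.T
    if mirna_ids is None:
        mirna_ids = [f"m{i}" for i in range(P.shape[0])]
    if disease_ids is None:
        disease_ids = [f"d{j}" for j in range(P.shape[1])]
    return ScoreMatrix(mirna_ids, disease_ids, P)
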