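"""Similarity kernel fusion: cross-diffusion of two similarity kernels.

Each kernel is column-normalized (the diffusion state) and row-normalized
over a k-nearest-neighbor support (the diffusion operator).  The iteration
mixes each kernel's state through its own neighbor operator with the other
kernel's state, anchored to the initial states by a weight tau.  The fused
kernel is the average of the final states, then masked by a neighbor
agreement matrix with entries {0, 0.5, 1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .data_model import SimilarityMatrix

__all__ = [
    "FusionParams",
    "FusionState",
    "default_k_neighbors",
    "normalize_kernel",
    "neighbor_kernel",
    "neighbor_sets",
    "fuse",
    "weight_matrix",
    "apply_weight",
    "fused_similarity",
]


def default_k_neighbors(n: int) -> int:
    return min(n, max(3, round(n / 10)))


@dataclass
class FusionParams:
    k_neighbors: int | None = None  # None -> max(3, round(n/10)), capped at n
    tau: float = 0.5
    max_iters: int = 20
    tol: float = 1e-6
    divisor_mode: Literal["literal-2", "n-minus-1"] = "literal-2"

    def __post_init__(self) -> None:
        if not (0.0 < self.tau < 1.0):
            raise ValueError("tau must lie in (0, 1)")
        if self.max_iters < 0:
            raise ValueError("max_iters must be >= 0")
        if self.tol < 0:
            raise ValueError("tol must be >= 0")
        if self.divisor_mode not in ("literal-2", "n-minus-1"):
            raise ValueError(f"unknown divisor_mode {self.divisor_mode!r}")

    def resolve_k(self, n: int) -> int:
        k = self.k_neighbors if self.k_neighbors is not None else default_k_neighbors(n)
        if not (1 <= k <= n):
            raise ValueError(f"k_neighbors={k} outside [1, {n}]")
        return k


@dataclass
class FusionState:
    ids: list[str]
    initial: list[np.ndarray]        # column-normalized kernels F_n^0
    neighbor: list[np.ndarray]       # row-normalized neighbor kernels S_n
    iterates: list[np.ndarray]       # final F_n
    overall: np.ndarray              # average of the final iterates
    weight: np.ndarray | None = None
    iterations: int = 0


def normalize_kernel(S: SimilarityMatrix | np.ndarray) -> np.ndarray:
    """Column-stochastic normalization: each entry divided by its column sum."""
    M = S.S if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    col_sums = M.sum(axis=0)
    if (col_sums <= 0).any():
        raise ValueError("kernel has a non-positive column sum; cannot normalize")
    return M / col_sums[np.newaxis, :]


def neighbor_sets(M: np.ndarray, k: int) -> list[np.ndarray]:
    """Indices of the k largest entries per row, self always included, ties by index."""
    n = M.shape[0]
    sets = []
    for i in range(n):
        # stable sort on (-value, index); force self in front
        keys = -M[i].copy()
        keys[i] = -np.inf
        order = np.argsort(keys, kind="stable")
        sets.append(np.sort(order[:k]))
    return sets

def neighbor_kernel(S: SimilarityMatrix | np.ndarray, k: int) -> np.ndarray:
    """Row-stochastic kernel restricted to each row's k-neighbor support."""
    M = S.S if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    n = M.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k={k} outside [1, {n}]")
    out = np.zeros_like(M)
    for i, nb in enumerate(neighbor_sets(M, k)):
        mass = M[i, nb].sum()
        if mass <= 0:
            raise ValueError(f"row {i}: zero similarity mass over its neighbor set")
        out[i, nb] = M[i, nb] / mass
    return out


def fuse(kernels: list[SimilarityMatrix], params: FusionParams | None = None) -> FusionState:
    """Run the cross-diffusion iteration on exactly two kernels."""
    params = params or FusionParams()
    if len(kernels) != 2:
        raise ValueError("fusion expects exactly two kernels")
    a, b = kernels
    if a.S.shape != b.S.shape or a.ids != b.ids:
        raise ValueError("kernels must share shape and identifiers")
    n = a.n
    k = params.resolve_k(n)
    divisor = 2.0 if params.divisor_mode == "literal-2" else float(max(len(kernels) - 1, 1))

    F0 = [normalize_kernel(K) for K in kernels]
    Sn = [neighbor_kernel(K, k) for K in kernels]
    F = [f.copy() for f in F0]
    anchor = [(1.0 - params.tau) * (sum(F0[t] for t in range(2) if t != nidx) / divisor)
              for nidx in range(2)]

    iters_done = 0
    for _ in range(params.max_iters):
        F_new = []
        for nidx in range(2):
            cross = sum(F[t] for t in range(2) if t != nidx) / divisor
            G = params.tau * (Sn[nidx] @ cross @ Sn[nidx].T) + anchor[nidx]
            F_new.append((G + G.T) / 2.0)
        delta = max(float(np.max(np.abs(F_new[t] - F[t]))) for t in range(2))
        F = F_new
        iters_done += 1
        if delta < params.tol:
            break

    overall = 0.5 * (F[0] + F[1])
    return FusionState(list(a.ids), F0, Sn, F, overall, iterations=iters_done)


def weight_matrix(S: SimilarityMatrix | np.ndarray, k: int) -> np.ndarray:
    """Neighbor-agreement mask: 1 for mutual neighbors, 0 for mutual strangers, 0.5 otherwise."""
    M = S.S if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    n = M.shape[0]
    member = np.zeros((n, n), dtype=bool)
    for i, nb in enumerate(neighbor_sets(M, k)):
        member[i, nb] = True  # member[i, j]: j is a neighbor of i
    in_both = member & member.T
    in_neither = ~member & ~member.T
    W = np.full((n, n), 0.5)
    W[in_both] = 1.0
    W[in_neither] = 0.0
    return W


def apply_weight(state: FusionState, k: int | None = None) -> SimilarityMatrix:
    """Mask the overall kernel entrywise by the agreement weights, then symmetrize."""
    if state.weight is None:
        if k is None:
            k = default_k_neighbors(len(state.ids))
        state.weight = weight_matrix(state.overall, k)
    if state.weight.shape != state.overall.shape:
        raise ValueError("weight matrix shape does not match the overall kernel")
    M = state.weight * state.overall
    return SimilarityMatrix(list(state.ids), (M + M.T) / 2.0)


def fused_similarity(
    k1: SimilarityMatrix, k2: SimilarityMatrix, params: FusionParams | None = None
) -> SimilarityMatrix:
    """Full fusion: diffuse, average, and apply the neighbor-agreement mask."""
    params = params or FusionParams()
    state = fuse([k1, k2], params)
    return apply_weight(state, params.resolve_k(k1.n))
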