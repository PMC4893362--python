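"""Least-squares rigid shape matching and goal-position machinery.

Each cluster matches its rest configuration x⁰ to the current particle
positions x by the rigid transform (R, t) minimising

    Σᵢ mᵢ ‖R (x⁰ᵢ − x⁰_cm) + x_cm − xᵢ‖²,

where the translations are the mass-weighted centres of mass of the two
configurations.  The optimal R is the orthonormal polar factor of the moment
matrix A = Σᵢ mᵢ (xᵢ − x_cm)(x⁰ᵢ − x⁰_cm)ᵀ, and the goal positions

    gᵢ = R (x⁰ᵢ − x⁰_cm) + x_cm

are the rigidly transformed rest shape.  Pulling each particle a fraction
α ∈ [0, 1] of the way towards its goal is the cluster stiffness constraint;
because the mass-weighted mean of the goals equals x_cm by construction, the
update conserves linear momentum exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sampling import Cluster

__all__ = [
    "ShapeMatchResult",
    "moment_matrix",
    "optimal_rotation",
    "optimal_rotation_batch",
    "goal_positions",
    "cluster_position_delta",
    "match_residual",
]

# relative threshold below which the moment matrix is treated as degenerate
_DEGENERATE_RTOL = 1e-9


@dataclass
class ShapeMatchResult:
    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    rest_com: np.ndarray  # (3,) mm
    com: np.ndarray  # (3,) mm, current mass-weighted centre
    goals: np.ndarray  # (k, 3) mm


def _weighted_com(positions: np.ndarray, masses: np.ndarray) -> np.ndarray:
    return (masses[:, None] * positions).sum(axis=0) / masses.sum()


def moment_matrix(
    rest: np.ndarray, current: np.ndarray, masses: np.ndarray
) -> np.ndarray:
    """Mass-weighted cross-covariance A = Σ mᵢ (xᵢ − x_cm)(x⁰ᵢ − x⁰_cm)ᵀ."""
    rest = np.asarray(rest, dtype=float).reshape(-1, 3)
    current = np.asarray(current, dtype=float).reshape(-1, 3)
    masses = np.asarray(masses, dtype=float).reshape(-1)
    p = current - _weighted_com(current, masses)
    q = rest - _weighted_com(rest, masses)
    return (masses[:, None] * p).T @ q


def optimal_rotation(
    A: np.ndarray, previous: np.ndarray | None = None
) -> np.ndarray:
    """Rotation (polar) factor of A with det = +1.

    Computed by SVD with a reflection fix: when det(U Vᵀ) < 0 the singular
    direction with the smallest singular value has its sign flipped.  For a
    rank-deficient A the rotation about the undetermined axis is resolved
    towards ``previous`` (warm start) when given, and towards the identity
    otherwise; an all-zero A returns ``previous`` or the identity.
    """
    A = np.asarray(A, dtype=float).reshape(3, 3)
    scale = np.abs(A).max()
    if scale < 1e-300:
        return np.eye(3) if previous is None else np.asarray(previous).copy()
    U, S, Vt = np.linalg.svd(A)
    if S[1] <= _DEGENERATE_RTOL * S[0]:
        # rank <= 1: bias the null space towards the warm-start rotation
        anchor = np.eye(3) if previous is None else np.asarray(previous)
        U, S, Vt = np.linalg.svd(A + (_DEGENERATE_RTOL * scale + 1e-300) * anchor)
    d = np.linalg.det(U @ Vt)
    if d < 0:
        U = U.copy()
        U[:, 2] *= -1.0
    return U @ Vt


def optimal_rotation_batch(
    A: np.ndarray,
    previous: np.ndarray | None = None,
    known_degenerate: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorised polar factors of a stack of (c, 3, 3) moment matrices.

    ``known_degenerate`` marks entries whose rank deficiency is structural
    (for example clusters with fewer than three non-collinear members); they
    are regularised towards the warm start up front, avoiding a second SVD
    pass every call.
    """
    A = np.asarray(A, dtype=float)
    if known_degenerate is not None and np.any(known_degenerate):
        anchor = (
            np.broadcast_to(np.eye(3), A[known_degenerate].shape)
            if previous is None
            else np.asarray(previous)[known_degenerate]
        )
        scale = np.abs(A[known_degenerate]).max(axis=(1, 2))
        A = A.copy()
        A[known_degenerate] += (
            (_DEGENERATE_RTOL * scale + 1e-300)[:, None, None] * anchor
        )
    U, S, Vt = np.linalg.svd(A)
    R = U @ Vt
    neg = np.linalg.det(R) < 0
    if np.any(neg):
        U = U.copy()
        U[neg, :, 2] *= -1.0
        R = U @ Vt
    # rank <= 1 clusters: re-solve with the warm-start bias, still batched
    scale = np.abs(A).max(axis=(1, 2))
    bad = (S[:, 1] <= _DEGENERATE_RTOL * np.maximum(S[:, 0], 1e-300)) | (
        scale < 1e-300
    )
    if np.any(bad):
        anchor = (
            np.broadcast_to(np.eye(3), A[bad].shape)
            if previous is None
            else np.asarray(previous)[bad]
        )
        delta = (_DEGENERATE_RTOL * scale[bad] + 1e-300)[:, None, None]
        Ub, _, Vtb = np.linalg.svd(A[bad] + delta * anchor)
        Rb = Ub @ Vtb
        negb = np.linalg.det(Rb) < 0
        if np.any(negb):
            Ub = Ub.copy()
            Ub[negb, :, 2] *= -1.0
            Rb = Ub @ Vtb
        R[bad] = Rb
    return R


def goal_positions(
    cluster: Cluster, current: np.ndarray, masses: np.ndarray
) -> ShapeMatchResult:
    """Best-fit rigid transform of the cluster's rest shape onto ``current``.

    ``current`` and ``masses`` are given for the cluster members only, in
    member order.  The mass-weighted mean of the returned goals equals the
    current centre of mass exactly.
    """
    current = np.asarray(current, dtype=float).reshape(-1, 3)
    masses = np.asarray(masses, dtype=float).reshape(-1)
    if len(current) != len(cluster):
        raise ValueError("current positions must cover all cluster members")
    com = _weighted_com(current, masses)
    rest_com = _weighted_com(cluster.rest_positions, masses)
    A = moment_matrix(cluster.rest_positions, current, masses)
    R = optimal_rotation(A, previous=cluster.rotation)
    goals = (cluster.rest_positions - rest_com) @ R.T + com
    return ShapeMatchResult(rotation=R, rest_com=rest_com, com=com, goals=goals)


def cluster_position_delta(
    goals: np.ndarray, current: np.ndarray, alpha: float
) -> np.ndarray:
    """Stiffness-scaled pull towards the goals: Δxᵢ = α (gᵢ − xᵢ)."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    return alpha * (np.asarray(goals, dtype=float) - np.asarray(current, dtype=float))


def match_residual(
    rest: np.ndarray, current: np.ndarray, masses: np.ndarray
) -> float:
    """Value of the shape-matching objective at the optimal rigid transform."""
    rest = np.asarray(rest, dtype=float).reshape(-1, 3)
    current = np.asarray(current, dtype=float).reshape(-1, 3)
    masses = np.asarray(masses, dtype=float).reshape(-1)
    com = _weighted_com(current, masses)
    rest_com = _weighted_com(rest, masses)
    A = moment_matrix(rest, current, masses)
    R = optimal_rotation(A)
    goals = (rest - rest_com) @ R.T + com
    return float((masses * ((goals - current) ** 2).sum(axis=1)).sum())
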