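"""Rigid coordinate registration guided by a transport plan.

The soft correspondence ``T`` weights every source-target spot pair, so the
optimal rotation/translation minimizing ``sum_ij T_ij ||R x_i + t - y_j||^2``
has the closed-form weighted Procrustes (Kabsch) solution via an SVD of the
weighted cross-covariance.  An optional ICP mode re-estimates hard
nearest-neighbor correspondences after each solve and iterates.

Reflections are projected out by the determinant sign correction (det R = +1);
an ``allow_reflection`` flag exists for genuinely flipped sections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .uot import TransportPlan

__all__ = ["RigidTransform", "Stack3D", "weighted_procrustes",
           "apply_transform", "stack_slices", "registration_residual"]


@dataclass
class RigidTransform:
    """Rotation ``R`` (2x2, det +1 unless reflections allowed) and
    translation ``t`` mapping source coordinates onto the target frame."""

    R: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        self.t = np.asarray(self.t, dtype=float).ravel()
        if self.R.shape != (2, 2) or self.t.shape != (2,):
            raise ValueError("R must be 2x2 and t length 2")
        if not np.allclose(self.R.T @ self.R, np.eye(2), atol=1e-8):
            raise ValueError("R is not orthogonal")

    @property
    def angle_deg(self) -> float:
        """Rotation angle in degrees, in (-180, 180]."""
        return float(np.degrees(np.arctan2(self.R[1, 0], self.R[0, 0])))

    def inverse(self) -> "RigidTransform":
        return RigidTransform(R=self.R.T, t=-self.R.T @ self.t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(R=np.eye(2), t=np.zeros(2))

    def to_record(self) -> list[float]:
        """Flat 6-number text record: R row-major then t."""
        return [*self.R.ravel().tolist(), *self.t.tolist()]

    @classmethod
    def from_record(cls, rec) -> "RigidTransform":
        rec = np.asarray(rec, dtype=float).ravel()
        return cls(R=rec[:4].reshape(2, 2), t=rec[4:6])


@dataclass
class Stack3D:
    """Slices registered to one reference and stacked along z."""

    coords: dict  # slice_id -> transformed (n x 2)
    z_offsets: dict  # slice_id -> z
    transforms: dict  # slice_id -> RigidTransform
    reference_slice_id: str

    def coords3d(self, slice_id: str) -> np.ndarray:
        xy = self.coords[slice_id]
        z = np.full((xy.shape[0], 1), self.z_offsets[slice_id])
        return np.hstack([xy, z])


def _kabsch(Xc: np.ndarray, Yc_weighted: np.ndarray,
            allow_reflection: bool) -> np.ndarray:
    """Rotation from the 2x2 weighted cross-covariance H = Xc^T (T Yc)."""
    H = Xc.T @ Yc_weighted
    if np.linalg.matrix_rank(H, tol=1e-12 * max(1.0, np.abs(H).max())) < 2:
        warnings.warn("rank-deficient cross-covariance (collinear points); "
                      "the rotation is poorly determined")
    U, _, Vt = np.linalg.svd(H)
    V = Vt.T
    if allow_reflection:
        return V @ U.T
    d = np.sign(np.linalg.det(V @ U.T))
    return V @ np.diag([1.0, d]) @ U.T


def weighted_procrustes(coords_x: np.ndarray, coords_y: np.ndarray,
                        plan: TransportPlan | np.ndarray,
                        allow_reflection: bool = False,
                        sparsify: bool = True,
                        icp_iters: int = 0) -> RigidTransform:
    """Optimal rigid map of source ``coords_x`` onto target ``coords_y``.

    Weights are the plan entries ``w_ij = T_ij``; weighted centroids are
    removed, the rotation comes from the SVD of the weighted cross-covariance
    and ``t = mu_y - R mu_x``.  Entries below ``1/(10 n_x n_y)`` are dropped
    for speed when ``sparsify`` (they are noise-level mass in an entropic
    plan).  ``icp_iters > 0`` switches to true ICP refinement afterwards:
    transform, re-match each source spot to its nearest target, re-solve.
    """
    X = np.asarray(coords_x, dtype=float)
    Y = np.asarray(coords_y, dtype=float)
    T = plan.T if isinstance(plan, TransportPlan) else np.asarray(plan, float)
    if T.shape != (X.shape[0], Y.shape[0]):
        raise ValueError("plan shape does not match coordinate counts")
    if sparsify:
        T = np.where(T >= 1.0 / (10.0 * T.size), T, 0.0)
    total = T.sum()
    if total <= 0:
        raise ValueError("transport plan has zero total mass")

    w_x = T.sum(axis=1)
    w_y = T.sum(axis=0)
    mu_x = (w_x @ X) / total
    mu_y = (w_y @ Y) / total
    Xc = X - mu_x
    Yc = Y - mu_y
    R = _kabsch(Xc, T @ Yc, allow_reflection)
    t = mu_y - R @ mu_x
    tf = RigidTransform(R=R, t=t)

    for _ in range(icp_iters):
        moved = apply_transform(X, tf)
        nn = cKDTree(Y).query(moved)[1]
        w = np.ones(X.shape[0])
        mu_x = (w @ X) / w.sum()
        mu_y = Y[nn].mean(axis=0)
        R = _kabsch(X - mu_x, Y[nn] - mu_y, allow_reflection)
        tf = RigidTransform(R=R, t=mu_y - R @ mu_x)
    return tf


def apply_transform(coords: np.ndarray, transform: RigidTransform) -> np.ndarray:
    """Rowwise ``R x + t``."""
    coords = np.asarray(coords, dtype=float)
    return coords @ transform.R.T + transform.t


def registration_residual(coords_x: np.ndarray, coords_y: np.ndarray,
                          plan: TransportPlan | np.ndarray,
                          transform: RigidTransform | None = None) -> float:
    """Weighted squared residual ``sum_ij T_ij ||R x_i + t - y_j||^2``."""
    X = np.asarray(coords_x, dtype=float)
    if transform is not None:
        X = apply_transform(X, transform)
    Y = np.asarray(coords_y, dtype=float)
    T = plan.T if isinstance(plan, TransportPlan) else np.asarray(plan, float)
    d2 = (np.sum(X**2, 1)[:, None] + np.sum(Y**2, 1)[None, :]
          - 2.0 * X @ Y.T)
    return float((T * np.maximum(d2, 0.0)).sum())


def stack_slices(results: list, reference_id: str,
                 z_spacing: float = 10.0) -> Stack3D:
    """Register every slice onto the reference and stack along z.

    ``results`` is a list of ``(slice, plan_to_reference)`` pairs in stack
    order; the reference slice's plan may be ``None`` (identity transform).
    The reference's coordinates define the common frame; z offsets are
    ordinal position times ``z_spacing``.
    """
    if z_spacing <= 0:
        raise ValueError("z_spacing must be positive")
    ids = [s.slice_id for s, _ in results]
    if reference_id not in ids:
        raise ValueError(f"reference {reference_id!r} not among slices")
    ref_slice = next(s for s, _ in results if s.slice_id == reference_id)

    coords, z_offsets, transforms = {}, {}, {}
    for ordinal, (s, plan) in enumerate(results):
        if s.slice_id == reference_id:
            tf = RigidTransform.identity()
        else:
            if plan is None:
                raise ValueError(
                    f"slice {s.slice_id!r} lacks a plan to the reference")
            tf = weighted_procrustes(s.coords, ref_slice.coords, plan)
        transforms[s.slice_id] = tf
        coords[s.slice_id] = apply_transform(s.coords, tf)
        z_offsets[s.slice_id] = ordinal * z_spacing
    return Stack3D(coords=coords, z_offsets=z_offsets, transforms=transforms,
                   reference_slice_id=reference_id)
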