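"""Superposition, RMSD and distance primitives.

These underlie frame clustering (pairwise RMSD matrices), the order
parameter's pre-fit, and all distance-cutoff contact criteria.  Everything is
in nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from .structure import SelectionMask, Trajectory

__all__ = [
    "RigidTransform",
    "RMSDMatrix",
    "kabsch_superpose",
    "rmsd_after_fit",
    "pairwise_rmsd_matrix",
    "min_distance",
]


@dataclass(frozen=True)
class RigidTransform:
    """A proper rotation plus translation: ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation determinant must be +1")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ np.asarray(self.rotation).T + np.asarray(
            self.translation
        )


@dataclass(frozen=True)
class RMSDMatrix:
    """Symmetric all-vs-all frame RMSD matrix (nm)."""

    values: np.ndarray
    frame_indices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RMSD matrix must be square")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("RMSD matrix diagonal must be zero")
        if np.any(np.abs(v - v.T) > 1e-9):
            raise ValueError("RMSD matrix must be symmetric")
        if np.any(v < 0):
            raise ValueError("RMSD values must be non-negative")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self):
        """Long-format (frame_i, frame_j, rmsd_nm) table for CSV export."""
        import pandas as pd

        i, j = np.triu_indices(self.n, k=1)
        return pd.DataFrame(
            {
                "frame_i": self.frame_indices[i],
                "frame_j": self.frame_indices[j],
                "rmsd_nm": self.values[i, j],
            }
        )


def _check_points(coords: np.ndarray, name: str) -> np.ndarray:
    c = np.asarray(coords, dtype=float)
    if c.ndim != 2 or c.shape[1] != 3:
        raise ValueError(f"{name} must be (n, 3)")
    return c


def kabsch_superpose(
    mobile_coords: np.ndarray,
    reference_coords: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper-rotation transform that minimizes the weighted RMSD
    and the RMSD value itself.  The reflection branch of the SVD solution is
    folded back to a proper rotation (det = +1).

    Raises on fewer than 3 points or a degenerate (collinear) reference.
    """
    P = _check_points(mobile_coords, "mobile_coords")
    Q = _check_points(reference_coords, "reference_coords")
    if P.shape != Q.shape:
        raise ValueError("point sets must have equal size")
    n = P.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()

    qc = (w[:, None] * Q).sum(axis=0)
    q0 = Q - qc
    # collinearity check on the reference spread
    if np.linalg.matrix_rank(q0, tol=1e-10) < 2:
        raise ValueError("reference points are collinear or coincident")
    pc = (w[:, None] * P).sum(axis=0)
    p0 = P - pc

    H = (w[:, None] * p0).T @ q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = p0 @ R.T - q0
    rmsd = float(np.sqrt((w * (diff**2).sum(axis=1)).sum()))
    return RigidTransform(R, t), rmsd


def _masked(coords: np.ndarray, mask: SelectionMask | np.ndarray | None) -> np.ndarray:
    if mask is None:
        return np.asarray(coords, dtype=float)
    if isinstance(mask, SelectionMask):
        idx = mask.as_array()
    else:
        idx = np.asarray(mask, dtype=int)
    if idx.size == 0:
        raise ValueError("empty selection mask")
    return np.asarray(coords, dtype=float)[idx]


def rmsd_after_fit(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    mask: SelectionMask | np.ndarray | None = None,
) -> float:
    """Minimum RMSD (nm) between two frames after optimal superposition.

    The same mask addresses both coordinate sets, so it must map to
    equal-size subsets by construction.
    """
    a = _masked(coords_a, mask)
    b = _masked(coords_b, mask)
    _, rmsd = kabsch_superpose(a, b)
    return rmsd


def pairwise_rmsd_matrix(
    trajectory: Trajectory,
    mask: SelectionMask | np.ndarray | None = None,
    frame_indices: np.ndarray | None = None,
) -> RMSDMatrix:
    """All-vs-all fitted RMSD over frames (upper triangle computed once)."""
    if frame_indices is None:
        frame_indices = np.arange(trajectory.n_frames)
    else:
        frame_indices = np.asarray(frame_indices, dtype=int)
    n = len(frame_indices)
    if n < 2:
        raise ValueError("pairwise RMSD needs at least 2 frames")
    subsets = [_masked(trajectory.frames[f], mask) for f in frame_indices]
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = rmsd_after_fit(subsets[i], subsets[j])
            values[i, j] = values[j, i] = r
    return RMSDMatrix(values, frame_indices)


def min_distance(
    coords: np.ndarray,
    mask_a: SelectionMask | np.ndarray,
    mask_b: SelectionMask | np.ndarray,
) -> float:
    """Exact minimum cross-pair distance (nm) between two disjoint atom groups."""
    ia = mask_a.as_array() if isinstance(mask_a, SelectionMask) else np.asarray(mask_a, int)
    ib = mask_b.as_array() if isinstance(mask_b, SelectionMask) else np.asarray(mask_b, int)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("min_distance requires two non-empty groups")
    if np.intersect1d(ia, ib).size:
        raise ValueError("atom groups overlap")
    c = np.asarray(coords, dtype=float)
    # exact contract: plain squared-distance scan, sqrt taken once at the end
    d2 = ((c[ia][:, None, :] - c[ib][None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min()))
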