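"""Rigid superposition: centering, optimal rotation via SVD, RMSD, and
the re-insertion transform used by the updating solvers.

The updating step rebuilds a metric base in a clean local frame from its
original distances and then maps base + new atom rigidly back onto the
base's current global coordinates.  The map is the Procrustes solution:
center both point sets, compute C = Y1ᵀ X1, take its SVD U Σ Vᵀ and use
Q = U Vᵀ.  Q may be improper (det −1): a freshly built canonical
tetrahedron can be the mirror image of the placed one, and only an
improper Q maps it onto the old base.  The global chirality is anchored
by the initial base and resolved at evaluation time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import RankDeficient

__all__ = ["RigidMap", "center", "optimal_rotation", "rmsd", "reinsert"]


@dataclass
class RigidMap:
    """x ↦ (x − source_centroid) @ rotation + target_centroid.

    ``rotation`` is orthogonal; det may be ±1.
    """

    rotation: np.ndarray
    source_centroid: np.ndarray
    target_centroid: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return (points - self.source_centroid) @ self.rotation + self.target_centroid


def center(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Translate a point set so its centroid is at the origin.

    Returns (centered points, centroid)."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or points.shape[0] < 1:
        raise ValueError("need an (n, 3) array with n >= 1")
    centroid = points.mean(axis=0)
    return points - centroid, centroid


def optimal_rotation(X1: np.ndarray, Y1: np.ndarray) -> np.ndarray:
    """Orthogonal Q minimizing ‖X1 − Y1 Q‖_F for centered point sets.

    Computed as Q = U Vᵀ from the SVD of C = Y1ᵀ X1.  Q may be improper
    (det −1).  When rank(C) < 2 the rotation is not unique; a
    :class:`RankDeficient` warning is issued and the SVD's deterministic
    output is returned.
    """
    X1 = np.asarray(X1, dtype=float)
    Y1 = np.asarray(Y1, dtype=float)
    if X1.shape != Y1.shape:
        raise ValueError("point sets must have equal shapes")
    C = Y1.T @ X1
    U, s, Vt = np.linalg.svd(C)
    if np.sum(s > 1e-12 * max(s[0], 1e-300)) < 2:
        warnings.warn(
            "cross-covariance rank < 2: rotation not unique", RankDeficient
        )
    return U @ Vt


def rmsd(X: np.ndarray, Y: np.ndarray) -> float:
    """Root-mean-square deviation between paired point sets (Å)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError("point sets must have equal shapes")
    return float(np.sqrt(np.mean(np.sum((X - Y) ** 2, axis=1))))


def fit_rigid_map(source: np.ndarray, target: np.ndarray) -> RigidMap:
    """Least-squares rigid (possibly improper) map taking ``source``
    points onto ``target`` points."""
    src_centered, src_c = center(source)
    tgt_centered, tgt_c = center(target)
    Q = optimal_rotation(tgt_centered, src_centered)
    return RigidMap(rotation=Q, source_centroid=src_c, target_centroid=tgt_c)


def reinsert(
    old_base_coords: np.ndarray, fresh_local_coords: np.ndarray
) -> np.ndarray:
    """Map a freshly rebuilt base + newly placed atom(s) back into the
    global structure.

    ``fresh_local_coords`` holds the base atoms first (as many as
    ``old_base_coords`` has rows) followed by the newly determined
    atom(s).  The rigid map is fitted from the fresh base onto the old
    base and applied to every fresh atom; the mapped base coordinates
    replace the old ones.
    """
    old_base_coords = np.asarray(old_base_coords, dtype=float)
    fresh_local_coords = np.asarray(fresh_local_coords, dtype=float)
    k = old_base_coords.shape[0]
    if fresh_local_coords.shape[0] < k:
        raise ValueError("fresh coordinates must contain the whole base")
    rigid = fit_rigid_map(fresh_local_coords[:k], old_base_coords)
    return rigid.apply(fresh_local_coords)
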