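"""Exact placement kernels.

The build-up solvers place one atom at a time from its distances to a
small set of already-positioned atoms.  Four non-coplanar reference
points determine the new point uniquely: squaring and subtracting the
four sphere equations

    ||x - x_i||^2 = d_i^2,   i = 1..4

leaves the 3x3 linear system  A x = b  with rows 2 (x_i - x_1)^T, which
is nonsingular exactly when the four points are non-coplanar.  Three
non-collinear references determine the point up to reflection across
their plane; a fourth, off-plane reference distance resolves the mirror
ambiguity.

All local-frame constructions use a fixed orientation convention (atom 1
at the origin, atom 2 on +x, atom 3 in the xy-plane with y >= 0, atom 4
with z >= 0) so identical distance inputs yield bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import (
    AmbiguousPlacement,
    DegenerateBase,
    InconsistentDistances,
    NoIntersection,
    NotRealizable,
)

__all__ = [
    "PlacementCandidatePair",
    "trilaterate4",
    "trilaterate3",
    "disambiguate",
    "init_tetrahedron",
    "init_triangle",
    "is_degenerate",
    "DEGENERACY_REL_TOL",
]

#: Relative threshold for the scaled determinant / cross-product
#: degeneracy tests.  Inputs are exact distances, so the window only has
#: to absorb floating-point round-off, but it must still reject the
#: "very flat tetrahedron" bases that amplify placement error.
DEGENERACY_REL_TOL = 1e-8


@dataclass
class PlacementCandidatePair:
    """The two mirror-image solutions of a 3-reference placement.

    ``p_plus`` and ``p_minus`` are reflections of each other across the
    base plane; they coincide when the target lies in that plane.
    """

    p_plus: np.ndarray
    p_minus: np.ndarray

    @property
    def coincident(self) -> bool:
        return bool(np.allclose(self.p_plus, self.p_minus, atol=1e-12))


def is_degenerate(coords: np.ndarray, rel_tol: float = DEGENERACY_REL_TOL) -> bool:
    """True if 4 points are (near-)coplanar or 3 points (near-)collinear.

    The test is scale-invariant: for four points the edge-vector
    determinant is compared against ``rel_tol`` times the product of the
    three edge norms; for three points the cross-product norm is compared
    against ``rel_tol`` times the product of the two edge norms.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape == (4, 3):
        e = coords[1:] - coords[0]
        scale = np.prod(np.linalg.norm(e, axis=1))
        if scale == 0.0:
            return True
        return bool(abs(np.linalg.det(e)) <= rel_tol * scale)
    if coords.shape == (3, 3):
        e1 = coords[1] - coords[0]
        e2 = coords[2] - coords[0]
        scale = np.linalg.norm(e1) * np.linalg.norm(e2)
        if scale == 0.0:
            return True
        return bool(np.linalg.norm(np.cross(e1, e2)) <= rel_tol * scale)
    raise ValueError("expected 3 or 4 points of shape (k, 3)")


def trilaterate4(
    base_coords: np.ndarray,
    dists: np.ndarray,
    rel_tol: float = DEGENERACY_REL_TOL,
    residual_tol: float = 1e-6,
) -> np.ndarray:
    """Place a point from its distances to four non-coplanar references.

    Solves the linear system obtained by squaring the four sphere
    equations and subtracting the first from the rest.

    Parameters
    ----------
    base_coords : (4, 3) array — reference coordinates.
    dists : (4,) array — distances from the new point to each reference.
    residual_tol : maximum allowed |‖x−x_i‖ − d_i| before the input
        distances are declared inconsistent.  Pass ``np.inf`` to disable
        the check (the plain GB solver does, since growing residuals are
        inherent to it).

    Raises
    ------
    DegenerateBase : references are near-coplanar.
    InconsistentDistances : a residual exceeds ``residual_tol``.
    """
    base_coords = np.asarray(base_coords, dtype=float)
    dists = np.asarray(dists, dtype=float)
    if base_coords.shape != (4, 3) or dists.shape != (4,):
        raise ValueError("need 4 reference points and 4 distances")
    if np.any(dists <= 0):
        raise ValueError("distances must be positive")
    if is_degenerate(base_coords, rel_tol):
        raise DegenerateBase("reference points are near-coplanar")

    x1 = base_coords[0]
    A = 2.0 * (base_coords[1:] - x1)
    sq = np.sum(base_coords**2, axis=1)
    b = (dists[0] ** 2 - dists[1:] ** 2) + (sq[1:] - sq[0])
    x = np.linalg.solve(A, b)

    residuals = np.abs(np.linalg.norm(base_coords - x, axis=1) - dists)
    worst = float(residuals.max())
    if worst > residual_tol:
        raise InconsistentDistances(
            f"placement residual {worst:.3e} Å exceeds tolerance {residual_tol:.1e}"
        )
    return x


def trilaterate3(
    base_coords: np.ndarray,
    dists: np.ndarray,
    rel_tol: float = DEGENERACY_REL_TOL,
    feasibility_tol: float = 1e-9,
) -> PlacementCandidatePair:
    """Both intersection points of three spheres around non-collinear
    centres.

    The base is mapped to its canonical in-plane frame, the in-plane
    coordinates are solved analytically, and the two out-of-plane
    solutions ±w are mapped back to the global frame.

    Raises
    ------
    DegenerateBase : centres are near-collinear.
    NoIntersection : the spheres do not intersect (w² < 0 beyond a
        round-off window scaled by the squared distances).
    """
    base_coords = np.asarray(base_coords, dtype=float)
    dists = np.asarray(dists, dtype=float)
    if base_coords.shape != (3, 3) or dists.shape != (3,):
        raise ValueError("need 3 reference points and 3 distances")
    if np.any(dists <= 0):
        raise ValueError("distances must be positive")
    if is_degenerate(base_coords, rel_tol):
        raise DegenerateBase("reference points are near-collinear")

    # orthonormal frame in the base plane, origin at the first point
    origin = base_coords[0]
    ex = base_coords[1] - origin
    x2 = np.linalg.norm(ex)
    ex = ex / x2
    v3 = base_coords[2] - origin
    x3 = float(ex @ v3)
    ey = v3 - x3 * ex
    y3 = np.linalg.norm(ey)
    ey = ey / y3
    ez = np.cross(ex, ey)

    d1, d2, d3 = dists
    u = (d1**2 - d2**2 + x2**2) / (2.0 * x2)
    v = (d1**2 - d3**2 + x3**2 + y3**2 - 2.0 * u * x3) / (2.0 * y3)
    w2 = d1**2 - u**2 - v**2
    scale = max(d1**2, d2**2, d3**2)
    if w2 < -feasibility_tol * scale:
        raise NoIntersection(
            f"spheres do not intersect: w² = {w2:.3e} (scale {scale:.3e})"
        )
    w = np.sqrt(max(w2, 0.0))
    in_plane = origin + u * ex + v * ey
    return PlacementCandidatePair(p_plus=in_plane + w * ez, p_minus=in_plane - w * ez)


def disambiguate(
    candidates: PlacementCandidatePair,
    ref_coord: np.ndarray,
    ref_dist: float,
    tol: float = 1e-6,
) -> np.ndarray:
    """Pick the mirror candidate consistent with a fourth, off-plane
    reference distance.

    Raises
    ------
    AmbiguousPlacement : both candidates match ``ref_dist`` within
        ``tol`` yet differ by more than ``tol`` — the reference atom is
        effectively coplanar with the base.
    InconsistentDistances : neither candidate matches.
    """
    ref_coord = np.asarray(ref_coord, dtype=float)
    err_plus = abs(np.linalg.norm(candidates.p_plus - ref_coord) - ref_dist)
    err_minus = abs(np.linalg.norm(candidates.p_minus - ref_coord) - ref_dist)
    separation = np.linalg.norm(candidates.p_plus - candidates.p_minus)
    if separation <= tol:
        return candidates.p_plus
    if err_plus <= tol and err_minus <= tol:
        raise AmbiguousPlacement(
            f"both candidates match the reference distance "
            f"(errors {err_plus:.3e}, {err_minus:.3e} Å; separation {separation:.3e} Å)"
        )
    if err_plus > tol and err_minus > tol:
        raise InconsistentDistances(
            f"neither candidate matches the reference distance "
            f"(errors {err_plus:.3e}, {err_minus:.3e} Å)"
        )
    return candidates.p_plus if err_plus < err_minus else candidates.p_minus


def init_triangle(
    d12: float, d13: float, d23: float, rel_tol: float = DEGENERACY_REL_TOL
) -> np.ndarray:
    """Canonical planar coordinates of a triangle from its side lengths.

    Atom 1 at the origin, atom 2 on +x, atom 3 in the xy-plane with
    y ≥ 0.  Raises :class:`DegenerateBase` when the triangle inequality
    holds only degenerately (collinear points).
    """
    if min(d12, d13, d23) <= 0:
        raise ValueError("distances must be positive")
    x3 = (d12**2 + d13**2 - d23**2) / (2.0 * d12)
    y3_sq = d13**2 - x3**2
    scale = max(d12, d13, d23) ** 2
    if y3_sq <= (rel_tol * scale) ** 2:
        raise DegenerateBase("triangle inequality fails or is degenerate")
    y3 = np.sqrt(y3_sq)
    return np.array([[0.0, 0.0, 0.0], [d12, 0.0, 0.0], [x3, y3, 0.0]])


def init_tetrahedron(
    dists: dict[tuple[int, int], float], rel_tol: float = DEGENERACY_REL_TOL
) -> np.ndarray:
    """Canonical coordinates of a tetrahedron from its six edge lengths.

    ``dists`` maps local index pairs (0,1), (0,2), (0,3), (1,2), (1,3),
    (2,3) to lengths.  Atom 1 sits at the origin, atom 2 on +x, atom 3
    in the xy-plane (y ≥ 0) and atom 4 above it (z ≥ 0).

    Raises
    ------
    DegenerateBase : the base triangle is degenerate.
    NotRealizable : no 3D embedding reproduces the six lengths (the
        squared height of atom 4 is negative beyond round-off), or the
        realization is flat.
    """
    try:
        d = {tuple(sorted(k)): float(v) for k, v in dists.items()}
        d12, d13, d14 = d[(0, 1)], d[(0, 2)], d[(0, 3)]
        d23, d24, d34 = d[(1, 2)], d[(1, 3)], d[(2, 3)]
    except KeyError as exc:
        raise ValueError("need all six pairwise distances") from exc

    tri = init_triangle(d12, d13, d23, rel_tol)
    x3, y3 = tri[2, 0], tri[2, 1]
    u = (d12**2 + d14**2 - d24**2) / (2.0 * d12)
    v = (x3**2 + y3**2 + d14**2 - d34**2 - 2.0 * u * x3) / (2.0 * y3)
    w_sq = d14**2 - u**2 - v**2
    scale = max(d.values()) ** 2
    if w_sq < -rel_tol * scale:
        raise NotRealizable(
            f"distance set is not embeddable in 3D (z² = {w_sq:.3e})"
        )
    w = np.sqrt(max(w_sq, 0.0))
    coords = np.vstack([tri, [u, v, w]])
    if is_degenerate(coords, rel_tol):
        raise NotRealizable("realization is flat (coplanar tetrahedron)")
    return coords
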