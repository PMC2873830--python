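"""The geometric build-up solvers: GB, UGB and RUGB.

All three share the same outer loop.  An initial metric base — four
atoms forming a 4-clique in the distance graph whose six mutual
distances embed as a non-degenerate tetrahedron — is placed in a
canonical frame.  The solver then sweeps the list of unpositioned atoms
in ascending id order, placing every atom for which a valid base is
found, until either all atoms are positioned or a full sweep makes no
progress.  A stalled run restarts from the next initial 4-clique (the
initial base is not guaranteed to reach every atom), up to a configured
number of attempts.

The three algorithms differ in how an atom is placed:

* **GB** — any four positioned, non-coplanar neighbours form the base;
  the atom is trilaterated directly from their *current* coordinates.
  Round-off in those coordinates feeds every later placement, so error
  accumulates — often catastrophically on sparse data.
* **UGB** — the base must additionally be a 4-clique of *original*
  distances.  It is rebuilt in a clean local frame from those distances,
  the atom is trilaterated there, and the five-atom complex (a K5 of
  known distances) is rigidly mapped back, replacing the base's stored
  coordinates.  Error no longer accumulates through base coordinates.
* **RUGB** — relaxes the base to a 3-clique of original distances plus
  one extra positioned, off-plane neighbour.  Three references leave a
  mirror ambiguity, which the extra atom's distance resolves.  The
  weaker condition makes bases far easier to find (the search touches
  only the atom's neighbour array, of length ≤ d_max) and updating
  applies more often.

When no all-original-distance base exists for an atom but four
positioned non-coplanar neighbours do, UGB and RUGB fall back to plain
(non-updated) trilateration; such placements are flagged in the
provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations, islice
from typing import Iterator, Optional

import numpy as np

from .core import (
    AdjacencyIndex,
    MetricBase,
    Placement,
    ReconstructionResult,
    SparseDistanceSet,
    Structure,
)
from .errors import (
    AmbiguousPlacement,
    DegenerateBase,
    GeobuildError,
    InconsistentDistances,
    NoInitialBase,
    NoIntersection,
    NotRealizable,
)
from .geometry import (
    DEGENERACY_REL_TOL,
    disambiguate,
    init_tetrahedron,
    init_triangle,
    is_degenerate,
    trilaterate3,
    trilaterate4,
)
from .graph import build_adjacency_index
from .superposition import reinsert

logger = logging.getLogger(__name__)

__all__ = [
    "SolverOptions",
    "solve",
    "find_initial_base",
    "iter_initial_bases",
    "iter_bases_4",
    "iter_bases_3plus1",
    "find_base_4",
    "find_base_3plus1",
    "place_atom_gb",
    "place_atom_ugb",
    "place_atom_rugb",
]

ALGORITHMS = ("gb", "ugb", "rugb")


@dataclass
class SolverOptions:
    """Tunable parameters of a build-up run.

    ``max_restarts`` bounds how many initial 4-cliques are tried before
    the solver settles for its best partial result; in the worst case
    every clique fails until the last one works.
    ``max_base_candidates`` caps how many candidate bases are examined
    per atom per sweep, bounding pathological enumeration on very dense
    neighbourhoods.  ``base_pool`` is the number of leading candidates
    collected and ranked by geometric conditioning before placement is
    attempted; flat bases amplify round-off sharply, so the
    best-conditioned available base is tried first.
    """

    algorithm: str = "rugb"
    degeneracy_rel_tol: float = DEGENERACY_REL_TOL
    distance_consistency_tol: float = 1e-6  # Å
    max_restarts: int = 25
    max_sweeps: Optional[int] = None
    initial_base: Optional[tuple[int, int, int, int]] = None
    max_base_candidates: int = 5000
    base_pool: int = 16

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.degeneracy_rel_tol <= 0 or self.distance_consistency_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_restarts < 1:
            raise ValueError("max_restarts must be >= 1")


# ---------------------------------------------------------------------------
# base search


def iter_initial_bases(
    idx: AdjacencyIndex,
    dset: SparseDistanceSet,
    rel_tol: float = DEGENERACY_REL_TOL,
) -> Iterator[tuple[int, int, int, int]]:
    """All 4-cliques of the distance graph whose six distances embed as a
    non-degenerate tetrahedron, in lexicographic order of the sorted id
    tuple.  Deterministic, so successive restarts draw distinct bases."""
    for i in range(idx.n):
        higher = [j for j, _ in idx.neighbours[i] if j > i]
        for j, k, l in combinations(higher, 3):
            if (j, k) not in dset or (j, l) not in dset or (k, l) not in dset:
                continue
            quad = (i, j, k, l)
            try:
                init_tetrahedron(_mutual_distances(quad, dset), rel_tol)
            except (DegenerateBase, NotRealizable):
                continue
            yield quad


def find_initial_base(
    idx: AdjacencyIndex,
    dset: SparseDistanceSet,
    start_hint: int = 0,
    rel_tol: float = DEGENERACY_REL_TOL,
) -> MetricBase:
    """The ``start_hint``-th valid initial 4-clique, realized in its
    canonical local frame.  Raises :class:`NoInitialBase` if exhausted."""
    for quad in islice(iter_initial_bases(idx, dset, rel_tol), start_hint, None):
        coords = init_tetrahedron(_mutual_distances(quad, dset), rel_tol)
        return MetricBase(base_ids=quad, base_coords=coords)
    raise NoInitialBase("no non-degenerate 4-clique found in the distance graph")


def _mutual_distances(
    ids: tuple[int, ...], dset: SparseDistanceSet
) -> dict[tuple[int, int], float]:
    """Original distances among a tuple of atoms, keyed by local index."""
    out: dict[tuple[int, int], float] = {}
    for (a, ia), (b, ib) in combinations(enumerate(ids), 2):
        d = dset.get(ia, ib)
        if d is None:
            raise KeyError(f"missing distance ({ia}, {ib})")
        out[(a, b)] = d
    return out


def iter_bases_4(
    atom: int,
    idx: AdjacencyIndex,
    positioned: np.ndarray,
    coords: np.ndarray,
    dset: SparseDistanceSet,
    require_clique: bool,
    rel_tol: float = DEGENERACY_REL_TOL,
    limit: int = 5000,
) -> Iterator[MetricBase]:
    """Candidate 4-atom bases for ``atom`` among its positioned
    neighbours, in lexicographic order.

    With ``require_clique`` (UGB) all six mutual distances must be
    original; without (GB and the fallback path) any four positioned
    neighbours qualify.  Either way the four current coordinates must be
    non-coplanar.
    """
    nbrs = [j for j, _ in idx.neighbours[atom] if positioned[j]]
    examined = 0
    for quad in combinations(nbrs, 4):
        if examined >= limit:
            return
        examined += 1
        if require_clique and any(
            pair not in dset for pair in combinations(quad, 2)
        ):
            continue
        pts = coords[list(quad)]
        if is_degenerate(pts, rel_tol):
            continue
        yield MetricBase(base_ids=quad, base_coords=pts)


def iter_bases_3plus1(
    atom: int,
    idx: AdjacencyIndex,
    positioned: np.ndarray,
    coords: np.ndarray,
    dset: SparseDistanceSet,
    rel_tol: float = DEGENERACY_REL_TOL,
    limit: int = 5000,
) -> Iterator[MetricBase]:
    """Candidate RUGB bases: a positioned neighbour triangle with all
    three mutual distances original, plus a positioned neighbour
    non-coplanar with it.  The search touches only ``atom``'s neighbour
    array (length ≤ d_max); triples in lexicographic order, extras in
    ascending id."""
    nbrs = [j for j, _ in idx.neighbours[atom] if positioned[j]]
    examined = 0
    for triple in combinations(nbrs, 3):
        if examined >= limit:
            return
        examined += 1
        if any(pair not in dset for pair in combinations(triple, 2)):
            continue
        tri_pts = coords[list(triple)]
        if is_degenerate(tri_pts, rel_tol):
            continue
        for extra in nbrs:
            if extra in triple:
                continue
            quad_pts = np.vstack([tri_pts, coords[extra]])
            if is_degenerate(quad_pts, rel_tol):
                continue
            yield MetricBase(base_ids=triple, base_coords=tri_pts, extra_id=extra)


def find_base_4(
    atom: int,
    idx: AdjacencyIndex,
    positioned: np.ndarray,
    coords: np.ndarray,
    dset: SparseDistanceSet,
    require_clique: bool = False,
    rel_tol: float = DEGENERACY_REL_TOL,
) -> Optional[MetricBase]:
    """First valid 4-atom base for ``atom``, or None."""
    return next(
        iter_bases_4(atom, idx, positioned, coords, dset, require_clique, rel_tol),
        None,
    )


def find_base_3plus1(
    atom: int,
    idx: AdjacencyIndex,
    positioned: np.ndarray,
    coords: np.ndarray,
    dset: SparseDistanceSet,
    rel_tol: float = DEGENERACY_REL_TOL,
) -> Optional[MetricBase]:
    """First valid 3+1 base for ``atom``, or None."""
    return next(
        iter_bases_3plus1(atom, idx, positioned, coords, dset, rel_tol), None
    )


# ---------------------------------------------------------------------------
# placement kernels


def place_atom_gb(
    atom: int,
    base: MetricBase,
    dset: SparseDistanceSet,
    rel_tol: float = DEGENERACY_REL_TOL,
) -> np.ndarray:
    """Plain trilateration from the base's current coordinates.

    No residual check: growing residuals are inherent to the
    non-updating algorithm and are measured at evaluation time."""
    dists = np.array([dset.get(atom, b) for b in base.base_ids], dtype=float)
    return trilaterate4(base.base_coords, dists, rel_tol, residual_tol=np.inf)


def place_atom_ugb(
    atom: int,
    base: MetricBase,
    dset: SparseDistanceSet,
    rel_tol: float = DEGENERACY_REL_TOL,
    tol: float = 1e-6,
) -> np.ndarray:
    """Updating placement from a 4-clique base.

    Rebuilds the base tetrahedron from its six original distances in a
    canonical frame, trilaterates the atom there from its four original
    distances, then rigidly maps the five-atom complex onto the old base
    coordinates.  Returns a (5, 3) array: the four refreshed base
    coordinates followed by the new atom.
    """
    if len(base.base_ids) != 4:
        raise ValueError("UGB placement needs a 4-atom base")
    local_base = init_tetrahedron(_mutual_distances(base.base_ids, dset), rel_tol)
    dists = np.array([dset.get(atom, b) for b in base.base_ids], dtype=float)
    local_new = trilaterate4(local_base, dists, rel_tol, residual_tol=tol)
    fresh = np.vstack([local_base, local_new])
    return reinsert(base.base_coords, fresh)


def place_atom_rugb(
    atom: int,
    base: MetricBase,
    extra_coord: np.ndarray,
    dset: SparseDistanceSet,
    rel_tol: float = DEGENERACY_REL_TOL,
    tol: float = 1e-6,
) -> np.ndarray:
    """Updating placement from a 3-clique base plus a disambiguating atom.

    Rebuilds the base triangle from its three original distances,
    intersects the three spheres in the local frame (two mirror
    candidates), maps triangle + both candidates back to the global
    frame, and picks the candidate whose distance to the extra atom
    matches the original.  Returns a (4, 3) array: the three refreshed
    base coordinates followed by the chosen new-atom position.

    Raises :class:`AmbiguousPlacement` when the extra atom cannot tell
    the candidates apart (near-coplanar reference); the caller rejects
    the base and keeps searching.
    """
    if len(base.base_ids) != 3 or base.extra_id is None:
        raise ValueError("RUGB placement needs a 3-atom base with an extra atom")
    i, j, k = base.base_ids
    local_base = init_triangle(dset.get(i, j), dset.get(i, k), dset.get(j, k), rel_tol)
    dists = np.array([dset.get(atom, b) for b in base.base_ids], dtype=float)
    cands = trilaterate3(local_base, dists, rel_tol)
    fresh = np.vstack([local_base, cands.p_plus, cands.p_minus])
    mapped = reinsert(base.base_coords, fresh)
    from .geometry import PlacementCandidatePair

    global_cands = PlacementCandidatePair(p_plus=mapped[3], p_minus=mapped[4])
    ref_dist = dset.get(atom, base.extra_id)
    chosen = disambiguate(global_cands, extra_coord, ref_dist, tol)
    chosen = _polish_against_references(
        chosen, np.vstack([mapped[:3], extra_coord]), np.append(dists, ref_dist), tol
    )
    return np.vstack([mapped[:3], chosen])


def _polish_against_references(
    x: np.ndarray, refs: np.ndarray, dists: np.ndarray, tol: float
) -> np.ndarray:
    """Damped Gauss–Newton least-squares refinement of a placed point
    against all of its original reference distances.

    The mirror-candidate construction determines the point from the
    three base distances alone; the disambiguating atom's distance is
    equally exact input, and distributing the residual over all four
    references reduces the error handed to later placements.  The step
    is a pure polish: it is skipped whenever it would move the point by
    more than a thousandth of ``tol``, which indicates genuinely
    inconsistent reference coordinates (e.g. perturbed input) rather
    than round-off — there the mirror-candidate placement itself is the
    contract and must not be dragged off the refreshed base."""
    step_cap = 1e-3 * tol
    for _ in range(2):
        diff = x - refs
        norms = np.linalg.norm(diff, axis=1)
        if np.any(norms == 0.0):
            break
        residuals = norms - dists
        J = diff / norms[:, None]
        step, *_ = np.linalg.lstsq(J, -residuals, rcond=None)
        if np.linalg.norm(step) > step_cap:
            break
        x = x + step
    return x


# ---------------------------------------------------------------------------
# base conditioning
#
# Placement error is amplified by flat bases: a near-coplanar tetrahedron
# makes the trilateration matrix ill-conditioned, and a thin base
# triangle (or a target atom close to the base plane) tilts the rigid
# re-insertion map.  Candidate bases are therefore ranked by a
# scale-invariant conditioning score in [0, 1] and tried best-first.


def tetrahedron_quality(pts: np.ndarray) -> float:
    """|det of edge vectors| / product of edge norms; 0 = flat."""
    e = pts[1:] - pts[0]
    scale = float(np.prod(np.linalg.norm(e, axis=1)))
    if scale == 0.0:
        return 0.0
    return float(abs(np.linalg.det(e)) / scale)


def triangle_quality(pts: np.ndarray) -> float:
    """Cross-product norm / product of edge norms; 0 = collinear."""
    e1, e2 = pts[1] - pts[0], pts[2] - pts[0]
    scale = float(np.linalg.norm(e1) * np.linalg.norm(e2))
    if scale == 0.0:
        return 0.0
    return float(np.linalg.norm(np.cross(e1, e2)) / scale)


def _positioned_neighbours(
    atom: int, idx: AdjacencyIndex, positioned: np.ndarray
) -> list[int]:
    return [j for j, _ in idx.neighbours[atom] if positioned[j]]


def _neighbour_triangles(
    nbrs: list[int], adj: list[set[int]], cap: int
) -> list[tuple[int, int, int]]:
    """Triples of ``nbrs`` whose three mutual distances are all original,
    in lexicographic order, at most ``cap`` of them."""
    out: list[tuple[int, int, int]] = []
    m = len(nbrs)
    for ia in range(m):
        a = nbrs[ia]
        adj_a = adj[a]
        for ib in range(ia + 1, m):
            b = nbrs[ib]
            if b not in adj_a:
                continue
            adj_b = adj[b]
            for ic in range(ib + 1, m):
                c = nbrs[ic]
                if c in adj_a and c in adj_b:
                    out.append((a, b, c))
                    if len(out) >= cap:
                        return out
    return out


def _triangle_qualities(
    triples: list[tuple[int, int, int]], coords: np.ndarray
) -> np.ndarray:
    T = np.asarray(triples)
    e1 = coords[T[:, 1]] - coords[T[:, 0]]
    e2 = coords[T[:, 2]] - coords[T[:, 0]]
    scale = np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.linalg.norm(np.cross(e1, e2), axis=1) / scale
    return np.nan_to_num(q)


def ranked_bases_3plus1(
    atom: int,
    idx: AdjacencyIndex,
    positioned: np.ndarray,
    coords: np.ndarray,
    dset: SparseDistanceSet,
    adj: list[set[int]],
    rel_tol: float = DEGENERACY_REL_TOL,
    cap: int = 5000,
    top_k: int = 16,
    disambiguation_tol: float = 1e-6,
) -> list[MetricBase]:
    """The best-conditioned RUGB bases for ``atom``, best first.

    Enumerates every all-original-distance neighbour triangle (up to
    ``cap``), ranks them by current-coordinate triangle quality, and for
    the leading ``top_k`` computes the full score — the worst of
    triangle quality and the best extra atom's normalized out-of-plane
    height.  The extra atom is the positioned neighbour farthest out of
    the base plane, relative to its distance.  Bases whose mirror
    candidates are neither clearly separable by the extra atom's
    distance nor effectively coincident are dropped: they would be
    rejected as ambiguous at placement time.
    """
    nbrs = _positioned_neighbours(atom, idx, positioned)
    if len(nbrs) < 4:
        return []
    triples = _neighbour_triangles(nbrs, adj, cap)
    if not triples:
        return []
    q_tri = _triangle_qualities(triples, coords)
    order = np.argsort(-q_tri, kind="stable")

    scored: list[tuple[float, int, MetricBase]] = []
    for rank, t in enumerate(order[:top_k]):
        if q_tri[t] <= rel_tol:
            break
        a, b, c = triples[t]
        tri_pts = coords[[a, b, c]]
        try:
            local = init_triangle(
                dset.get(a, b), dset.get(a, c), dset.get(b, c), rel_tol
            )
            dists = np.array(
                [dset.get(atom, x) for x in (a, b, c)], dtype=float
            )
            cands = trilaterate3(local, dists, rel_tol)
        except GeobuildError:
            continue
        separation = 2.0 * abs(float(cands.p_plus[2]))

        normal = np.cross(tri_pts[1] - tri_pts[0], tri_pts[2] - tri_pts[0])
        normal /= np.linalg.norm(normal)
        best_extra: Optional[tuple[float, int]] = None
        for x in nbrs:
            if x == a or x == b or x == c:
                continue
            v = coords[x] - tri_pts[0]
            h = abs(float(normal @ v)) / float(np.linalg.norm(v))
            if h > rel_tol and (best_extra is None or h > best_extra[0]):
                best_extra = (h, x)
        if best_extra is None:
            continue
        # projected distance gap between the two candidates as seen from
        # the extra atom must clear the consistency tolerance, unless the
        # candidates effectively coincide
        if not (separation * best_extra[0] > 4.0 * disambiguation_tol
                or separation <= disambiguation_tol):
            continue
        score = min(float(q_tri[t]), best_extra[0])
        scored.append(
            (
                score,
                rank,
                MetricBase(
                    base_ids=(a, b, c), base_coords=tri_pts, extra_id=best_extra[1]
                ),
            )
        )
    scored.sort(key=lambda z: (-z[0], z[1]))
    return [base for _, _, base in scored]


def ranked_bases_4(
    atom: int,
    idx: AdjacencyIndex,
    positioned: np.ndarray,
    coords: np.ndarray,
    dset: SparseDistanceSet,
    adj: list[set[int]],
    require_clique: bool,
    rel_tol: float = DEGENERACY_REL_TOL,
    cap: int = 5000,
    top_k: int = 16,
) -> list[MetricBase]:
    """The best-conditioned 4-atom bases for ``atom``, best first,
    ranked by normalized tetrahedron volume of the current coordinates.

    With ``require_clique`` the quads are built by extending
    all-original-distance triangles with a common neighbour (UGB);
    without, any four positioned neighbours qualify (GB and fallback).
    """
    nbrs = _positioned_neighbours(atom, idx, positioned)
    if len(nbrs) < 4:
        return []
    quads: list[tuple[int, int, int, int]] = []
    if require_clique:
        for a, b, c in _neighbour_triangles(nbrs, adj, cap):
            common = adj[a] & adj[b] & adj[c]
            for x in nbrs:
                if x > c and x in common:
                    quads.append((a, b, c, x))
                    if len(quads) >= cap:
                        break
            if len(quads) >= cap:
                break
    else:
        quads = list(islice(combinations(nbrs, 4), cap))
    if not quads:
        return []
    Q = np.asarray(quads)
    e = coords[Q[:, 1:]] - coords[Q[:, 0]][:, None, :]
    scale = np.prod(np.linalg.norm(e, axis=2), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.abs(np.linalg.det(e)) / scale
    q = np.nan_to_num(q)
    order = np.argsort(-q, kind="stable")
    out = []
    for t in order[:top_k]:
        if q[t] <= rel_tol:
            break
        ids = quads[t]
        out.append(MetricBase(base_ids=ids, base_coords=coords[list(ids)]))
    return out


# ---------------------------------------------------------------------------
# the outer loop


@dataclass
class _RunState:
    coords: np.ndarray
    positioned: np.ndarray
    adj: list[set[int]]
    provenance: dict[int, Placement] = field(default_factory=dict)


def _try_place(
    atom: int,
    state: _RunState,
    idx: AdjacencyIndex,
    dset: SparseDistanceSet,
    opts: SolverOptions,
    sweep: int,
    restart: int,
) -> bool:
    """Attempt to place one atom; True on success.  Tries successive
    candidate bases when a base is rejected for degeneracy, ambiguity or
    inconsistency."""
    rel_tol = opts.degeneracy_rel_tol
    tol = opts.distance_consistency_tol
    cap = opts.max_base_candidates
    pool = opts.base_pool

    if opts.algorithm == "rugb":
        for base in ranked_bases_3plus1(
            atom, idx, state.positioned, state.coords, dset, state.adj,
            rel_tol, cap, pool, disambiguation_tol=tol,
        ):
            try:
                out = place_atom_rugb(
                    atom, base, state.coords[base.extra_id], dset, rel_tol, tol
                )
            except (AmbiguousPlacement, DegenerateBase, NotRealizable,
                    NoIntersection, InconsistentDistances):
                continue
            state.coords[list(base.base_ids)] = out[:3]
            state.coords[atom] = out[3]
            state.positioned[atom] = True
            state.provenance[atom] = Placement(
                base.base_ids, base.extra_id, sweep, restart, updated=True
            )
            return True

    if opts.algorithm == "ugb":
        for base in ranked_bases_4(
            atom, idx, state.positioned, state.coords, dset, state.adj,
            require_clique=True, rel_tol=rel_tol, cap=cap, top_k=pool,
        ):
            try:
                out = place_atom_ugb(atom, base, dset, rel_tol, tol)
            except (DegenerateBase, NotRealizable, InconsistentDistances):
                continue
            state.coords[list(base.base_ids)] = out[:4]
            state.coords[atom] = out[4]
            state.positioned[atom] = True
            state.provenance[atom] = Placement(
                base.base_ids, None, sweep, restart, updated=True
            )
            return True

    # GB placement; also the non-updated fallback for UGB/RUGB.
    for base in ranked_bases_4(
        atom, idx, state.positioned, state.coords, dset, state.adj,
        require_clique=False, rel_tol=rel_tol, cap=cap, top_k=pool,
    ):
        try:
            pos = place_atom_gb(atom, base, dset, rel_tol)
        except DegenerateBase:
            continue
        state.coords[atom] = pos
        state.positioned[atom] = True
        state.provenance[atom] = Placement(
            base.base_ids, None, sweep, restart, updated=False
        )
        return True
    return False


def solve(dset: SparseDistanceSet, opts: Optional[SolverOptions] = None) -> ReconstructionResult:
    """Reconstruct coordinates from a sparse exact distance set.

    Returns a :class:`ReconstructionResult` with status ``complete``
    (every atom positioned), ``partial`` (the largest positioned set
    found over all restarts) or ``failed`` (no valid initial base).
    The output frame is arbitrary up to a rigid motion and possibly a
    reflection; compare against a reference with
    :func:`geobuild.evaluation.aligned_rmsd`.
    """
    opts = opts or SolverOptions()
    n = dset.n
    if n < 4:
        raise ValueError("need at least 4 atoms")
    idx = build_adjacency_index(dset)
    adj = [set(ids) for ids in (idx.neighbour_ids(i) for i in range(n))]

    base_iter = iter_initial_bases(idx, dset, opts.degeneracy_rel_tol)
    best: Optional[_RunState] = None
    best_meta: tuple[tuple[int, ...], int, int] = ((), 0, 0)
    restart = 0

    while restart < opts.max_restarts:
        if opts.initial_base is not None and restart == 0:
            quad = tuple(sorted(opts.initial_base))
            try:
                local = init_tetrahedron(
                    _mutual_distances(quad, dset), opts.degeneracy_rel_tol
                )
            except (KeyError, GeobuildError) as exc:
                raise NoInitialBase(f"explicit initial base invalid: {exc}") from exc
        else:
            try:
                quad = next(base_iter)
            except StopIteration:
                break
            local = init_tetrahedron(
                _mutual_distances(quad, dset), opts.degeneracy_rel_tol
            )

        state = _RunState(
            coords=np.zeros((n, 3)), positioned=np.zeros(n, dtype=bool), adj=adj
        )
        state.coords[list(quad)] = local
        state.positioned[list(quad)] = True

        sweep = 0
        while not state.positioned.all():
            if opts.max_sweeps is not None and sweep >= opts.max_sweeps:
                break
            sweep += 1
            progress = 0
            for atom in np.flatnonzero(~state.positioned):
                if _try_place(int(atom), state, idx, dset, opts, sweep, restart):
                    progress += 1
            logger.debug(
                "restart %d sweep %d: placed %d atoms (%d/%d positioned)",
                restart, sweep, progress, int(state.positioned.sum()), n,
            )
            if progress == 0:
                break

        if best is None or state.positioned.sum() > best.positioned.sum():
            best = state
            best_meta = (quad, restart, sweep)
        if state.positioned.all():
            break
        restart += 1

    if best is None:
        return ReconstructionResult(
            structure=Structure(coords=np.zeros((n, 3))),
            positioned_mask=np.zeros(n, dtype=bool),
            status="failed",
            restart_count=0,
            algorithm=opts.algorithm,
        )

    status = "complete" if best.positioned.all() else "partial"
    quad, used_restart, sweeps = best_meta
    logger.info(
        "%s: status=%s positioned=%d/%d restarts=%d sweeps=%d",
        opts.algorithm, status, int(best.positioned.sum()), n, used_restart, sweeps,
    )
    return ReconstructionResult(
        structure=Structure(coords=best.coords),
        positioned_mask=best.positioned,
        status=status,
        provenance=best.provenance,
        initial_base=quad,
        restart_count=used_restart,
        sweep_count=sweeps,
        algorithm=opts.algorithm,
    )
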