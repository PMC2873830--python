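"""Domain types shared by all build-up solvers.

Coordinates are in ångström throughout.  Atom ids are dense 0-based
integers internally; all file formats use 1-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Structure",
    "SparseDistanceSet",
    "AdjacencyIndex",
    "MetricBase",
    "ReconstructionResult",
]


@dataclass
class Structure:
    """An ordered list of atoms with 3D coordinates.

    Parameters
    ----------
    coords : (n, 3) float array, ångström.
    labels : optional per-atom metadata (atom name, residue name,
        residue number) carried through from a coordinate file.
    """

    coords: np.ndarray
    labels: Optional[list[tuple]] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.labels is not None and len(self.labels) != len(self.coords):
            raise ValueError("labels length must match atom count")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def atom_ids(self) -> np.ndarray:
        return np.arange(self.n_atoms)

    def __len__(self) -> int:
        return self.n_atoms


@dataclass
class SparseDistanceSet:
    """A molecular distance geometry instance: the exact distances known
    to the solver, stored once per unordered pair (i < j).
    """

    n: int
    entries: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (i, j), d in self.entries.items():
            self._validate(i, j, d)

    def _validate(self, i: int, j: int, d: float) -> None:
        if not (0 <= i < j < self.n):
            raise ValueError(f"invalid pair ({i}, {j}) for n={self.n}")
        if not d > 0:
            raise ValueError(f"distance for pair ({i}, {j}) must be > 0")

    def add(self, i: int, j: int, d: float) -> None:
        if i > j:
            i, j = j, i
        self._validate(i, j, d)
        key = (i, j)
        if key in self.entries:
            raise ValueError(f"duplicate pair {key}")
        self.entries[key] = float(d)

    def get(self, i: int, j: int) -> Optional[float]:
        """Distance for the unordered pair, or None if unknown."""
        if i > j:
            i, j = j, i
        return self.entries.get((i, j))

    def __contains__(self, pair: tuple[int, int]) -> bool:
        i, j = pair
        if i > j:
            i, j = j, i
        return (i, j) in self.entries

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class AdjacencyIndex:
    """Per-atom neighbour arrays over a sparse distance set.

    ``neighbours[i]`` is a list of ``(j, d_ij)`` sorted by neighbour id;
    the symmetric counterpart is stored under ``neighbours[j]`` with the
    same distance.  ``d_max`` is the maximum degree, the quantity that
    bounds the per-atom base-search cost of the revised solver.
    """

    n: int
    neighbours: list[list[tuple[int, float]]]
    degrees: np.ndarray
    d_max: int

    def neighbour_ids(self, i: int) -> list[int]:
        return [j for j, _ in self.neighbours[i]]

    def distance(self, i: int, j: int) -> Optional[float]:
        """Distance between i and j if the pair is indexed, else None."""
        for k, d in self.neighbours[i]:
            if k == j:
                return d
            if k > j:
                return None
        return None


@dataclass
class MetricBase:
    """The positioned atoms used to place one unpositioned atom.

    Either four non-coplanar atoms (GB/UGB), or three non-collinear atoms
    plus a disambiguating ``extra_id`` that is non-coplanar with them
    (RUGB).  ``base_coords`` are the atoms' current global coordinates in
    ``base_ids`` order.
    """

    base_ids: tuple[int, ...]
    base_coords: np.ndarray
    extra_id: Optional[int] = None

    def __post_init__(self) -> None:
        self.base_coords = np.asarray(self.base_coords, dtype=float)
        k = len(self.base_ids)
        if k not in (3, 4):
            raise ValueError("a metric base has 3 or 4 atoms")
        if self.base_coords.shape != (k, 3):
            raise ValueError("base_coords shape must match base_ids")
        if k == 3 and self.extra_id is None:
            raise ValueError("a 3-atom base requires a disambiguating atom")


@dataclass
class Placement:
    """Provenance of one positioned atom: which base placed it, during
    which sweep of which restart, and whether the updating step ran."""

    base_ids: tuple[int, ...]
    extra_id: Optional[int]
    sweep: int
    restart: int
    updated: bool


@dataclass
class ReconstructionResult:
    """Outcome of a build-up run.

    ``structure`` holds coordinates for all atoms; only rows where
    ``positioned_mask`` is True are meaningful.  ``provenance`` maps each
    positioned atom beyond the initial base to its :class:`Placement`.
    """

    structure: Structure
    positioned_mask: np.ndarray
    status: str  # "complete" | "partial" | "failed"
    provenance: dict[int, Placement] = field(default_factory=dict)
    initial_base: Optional[tuple[int, ...]] = None
    restart_count: int = 0
    sweep_count: int = 0
    algorithm: str = ""

    def __post_init__(self) -> None:
        self.positioned_mask = np.asarray(self.positioned_mask, dtype=bool)
        if self.status not in ("complete", "partial", "failed"):
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "complete" and not self.positioned_mask.all():
            raise ValueError("status 'complete' requires all atoms positioned")

    @property
    def n_positioned(self) -> int:
        return int(self.positioned_mask.sum())

    def positioned_ids(self) -> np.ndarray:
        return np.flatnonzero(self.positioned_mask)
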