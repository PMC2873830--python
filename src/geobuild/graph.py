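"""Cutoff distance graphs and the adjacency index.

A sparse instance is derived from a known structure by keeping every
pairwise distance up to a cutoff (5 Å emulates NMR-observable proton
contacts; 8 Å gives a denser graph).  The adjacency index materializes
per-atom neighbour arrays whose lengths are bounded by the maximum
degree d_max — the quantity that makes the revised base search cheap,
since d_max ≪ n for protein-like cutoff graphs.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import AdjacencyIndex, SparseDistanceSet, Structure

__all__ = [
    "build_distance_set",
    "build_adjacency_index",
    "degree_stats",
    "has_distance",
    "adjacency_to_distance_set",
]


def build_distance_set(structure: Structure, cutoff: float) -> SparseDistanceSet:
    """All unordered atom pairs with Euclidean distance ≤ cutoff (Å),
    at full double precision.  Inclusive comparison: only pairs strictly
    larger than the cutoff are dropped."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = structure.n_atoms
    dmat = squareform(pdist(structure.coords))
    iu, ju = np.triu_indices(n, k=1)
    keep = dmat[iu, ju] <= cutoff
    entries = {
        (int(i), int(j)): float(dmat[i, j])
        for i, j in zip(iu[keep], ju[keep])
    }
    return SparseDistanceSet(n=n, entries=entries)


def build_adjacency_index(dset: SparseDistanceSet) -> AdjacencyIndex:
    """Symmetric per-atom neighbour arrays, sorted by neighbour id."""
    neighbours: list[list[tuple[int, float]]] = [[] for _ in range(dset.n)]
    for (i, j), d in dset.entries.items():
        neighbours[i].append((j, d))
        neighbours[j].append((i, d))
    for arr in neighbours:
        arr.sort()
    degrees = np.array([len(arr) for arr in neighbours], dtype=int)
    d_max = int(degrees.max()) if dset.n else 0
    return AdjacencyIndex(n=dset.n, neighbours=neighbours, degrees=degrees, d_max=d_max)


def degree_stats(idx: AdjacencyIndex) -> tuple[int, int, float]:
    """(n, d_max, d_max/n) — the sparsity summary of an instance."""
    ratio = idx.d_max / idx.n if idx.n else 0.0
    return idx.n, idx.d_max, ratio


def has_distance(idx: AdjacencyIndex, i: int, j: int) -> Optional[float]:
    """Distance for the unordered pair (i, j) if indexed, else None."""
    if not (0 <= i < idx.n and 0 <= j < idx.n):
        raise ValueError("atom id out of range")
    return idx.distance(i, j)


def adjacency_to_distance_set(idx: AdjacencyIndex) -> SparseDistanceSet:
    """Inverse of :func:`build_adjacency_index` (exact round-trip)."""
    entries: dict[tuple[int, int], float] = {}
    for i, arr in enumerate(idx.neighbours):
        for j, d in arr:
            if i < j:
                entries[(i, j)] = d
    return SparseDistanceSet(n=idx.n, entries=entries)
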