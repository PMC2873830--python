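"""Synthetic protein-like test instances.

Real test data for distance-geometry solvers comes from PDB structures
cut at an NMR-like distance threshold.  This module generates stand-in
structures with the same gross geometry — protein-scale packing density
and chain connectivity — so the solvers are exercisable without any
downloads:

* **chain** mode grows a self-avoiding persistent random walk with a
  fixed bond length (1.5 Å, a generic covalent bond) and an excluded
  volume of 1.0 Å, mimicking a polypeptide heavy-atom trace.  Its 5 Å
  cutoff graphs have d_max/n ratios in the same range as all-atom
  protein graphs (~0.04–0.13).
* **cloud** mode samples points uniformly in a cube sized for a mean
  density of ~0.05 atoms/Å³ (protein interior packing), rejecting pairs
  closer than the minimum separation.

``generate_solvable_instance`` additionally certifies — by a purely
combinatorial dry run of the relaxed base-existence check — that a
build-up ordering positioning every atom exists, enlarging the cutoff
by 10 % steps when it does not.  Geometric degeneracies (flat bases)
are left to runtime and surface as solver restarts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .core import SparseDistanceSet, Structure
from .errors import GenerationFailure
from .graph import build_adjacency_index, build_distance_set

__all__ = [
    "GeneratorConfig",
    "generate_structure",
    "generate_solvable_instance",
    "perturb_coordinates",
]

#: Mean packing density of protein interiors, atoms per Å³.
PROTEIN_DENSITY = 0.05


@dataclass
class GeneratorConfig:
    n: int = 300
    mode: str = "chain"  # "chain" | "cloud"
    bond_length: float = 1.5  # Å, chain mode
    min_separation: float = 1.0  # Å, excluded volume
    cutoff: float = 5.0  # Å
    direction_jitter: float = 0.9  # chain persistence; higher = more compact
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 5:
            raise ValueError("need at least 5 atoms")
        if self.mode not in ("chain", "cloud"):
            raise ValueError("mode must be 'chain' or 'cloud'")
        if not self.min_separation < self.cutoff:
            raise ValueError("min_separation must be below the cutoff")


def generate_structure(cfg: GeneratorConfig) -> Structure:
    """Deterministic (per seed) protein-like point set."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.mode == "cloud":
        return _generate_cloud(cfg, rng)
    return _generate_chain(cfg, rng)


def _generate_cloud(cfg: GeneratorConfig, rng: np.random.Generator) -> Structure:
    side = (cfg.n / PROTEIN_DENSITY) ** (1.0 / 3.0)
    coords: list[np.ndarray] = []
    attempts = 0
    max_attempts = 200 * cfg.n
    while len(coords) < cfg.n:
        if attempts >= max_attempts:
            raise GenerationFailure(
                f"cloud rejection sampling exhausted after {attempts} attempts"
            )
        attempts += 1
        p = rng.uniform(0.0, side, size=3)
        if coords:
            d = np.linalg.norm(np.asarray(coords) - p, axis=1)
            if d.min() < cfg.min_separation:
                continue
        coords.append(p)
    return Structure(coords=np.asarray(coords))


def _generate_chain(cfg: GeneratorConfig, rng: np.random.Generator) -> Structure:
    """Self-avoiding persistent random walk with fixed bond length.

    Each step direction is the previous direction plus isotropic
    Gaussian jitter, renormalized; steps closer than the excluded-volume
    radius to any earlier atom are re-drawn.  A stuck walk backtracks a
    few steps before giving up.
    """
    max_restarts = 20
    for _ in range(max_restarts):
        coords = np.zeros((cfg.n, 3))
        direction = _random_unit(rng)
        i = 1
        stuck = 0
        while i < cfg.n:
            placed = False
            for _attempt in range(60):
                jitter = cfg.direction_jitter * rng.standard_normal(3)
                cand_dir = direction + jitter
                cand_dir /= np.linalg.norm(cand_dir)
                cand = coords[i - 1] + cfg.bond_length * cand_dir
                d = np.linalg.norm(coords[: i - 1] - cand, axis=1) if i > 1 else np.array([np.inf])
                if d.min() >= cfg.min_separation:
                    coords[i] = cand
                    direction = cand_dir
                    placed = True
                    break
            if placed:
                i += 1
            else:
                # backtrack a few bonds and retry from there
                i = max(1, i - 5)
                direction = _random_unit(rng)
                stuck += 1
                if stuck > 50:
                    break
        if i == cfg.n:
            return Structure(coords=coords)
    raise GenerationFailure("self-avoiding walk failed to reach the target length")


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def perturb_coordinates(structure: Structure, sigma: float, seed: int = 0) -> Structure:
    """Add isotropic Gaussian noise of standard deviation ``sigma`` (Å)
    per coordinate; used to probe error propagation through placements."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=structure.coords.shape) if sigma > 0 else 0.0
    return Structure(coords=structure.coords + noise, labels=structure.labels)


# ---------------------------------------------------------------------------
# solvability certification (combinatorial only)


def _buildup_reachable(dset: SparseDistanceSet) -> bool:
    """True if a build-up ordering positioning every atom exists, under
    the relaxed (3-clique + extra neighbour) base condition.

    Pure graph search: starts from the first 4-clique, then repeatedly
    marks any atom that has three mutually-adjacent positioned
    neighbours plus a fourth positioned neighbour.  Geometry (collinear
    or coplanar bases) is deliberately ignored here.
    """
    idx = build_adjacency_index(dset)
    seed = _first_clique(idx, dset)
    if seed is None:
        return False
    positioned = np.zeros(dset.n, dtype=bool)
    positioned[list(seed)] = True
    progress = True
    while progress and not positioned.all():
        progress = False
        for atom in np.flatnonzero(~positioned):
            nbrs = [j for j, _ in idx.neighbours[atom] if positioned[j]]
            if len(nbrs) < 4:
                continue
            if _has_triangle_plus_one(nbrs, dset):
                positioned[atom] = True
                progress = True
    return bool(positioned.all())


def _first_clique(idx, dset) -> tuple[int, ...] | None:
    for i in range(idx.n):
        higher = [j for j, _ in idx.neighbours[i] if j > i]
        for j, k, l in combinations(higher, 3):
            if (j, k) in dset and (j, l) in dset and (k, l) in dset:
                return (i, j, k, l)
    return None


def _has_triangle_plus_one(nbrs: list[int], dset: SparseDistanceSet) -> bool:
    for triple in combinations(nbrs, 3):
        if all(pair in dset for pair in combinations(triple, 2)):
            if len(nbrs) > 3:  # any fourth positioned neighbour will do
                return True
    return False


def generate_solvable_instance(
    cfg: GeneratorConfig, max_cutoff_growth: int = 5
) -> tuple[Structure, SparseDistanceSet, float]:
    """A ground-truth structure and a cutoff distance set certified
    build-up-reachable.

    If the cutoff graph at ``cfg.cutoff`` is not reachable, the cutoff
    grows by 10 % up to ``max_cutoff_growth`` times.  Returns
    (structure, distance set, cutoff actually used).
    """
    structure = generate_structure(cfg)
    cutoff = cfg.cutoff
    for _ in range(max_cutoff_growth + 1):
        dset = build_distance_set(structure, cutoff)
        if _buildup_reachable(dset):
            return structure, dset, cutoff
        cutoff *= 1.1
    raise GenerationFailure(
        f"no solvable cutoff graph found up to {cutoff / 1.1:.2f} Å "
        f"(seed {cfg.seed}, n {cfg.n})"
    )
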