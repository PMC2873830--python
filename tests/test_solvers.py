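"""Build-up solvers: base search, placement kernels, full runs."""

from itertools import combinations

import numpy as np
import pytest

from geobuild.core import MetricBase, SparseDistanceSet, Structure
from geobuild.errors import AmbiguousPlacement, NoInitialBase
from geobuild.evaluation import aligned_rmsd, max_distance_violation
from geobuild.geometry import is_degenerate
from geobuild.graph import build_adjacency_index, build_distance_set
from geobuild.solvers import (
    SolverOptions,
    find_base_3plus1,
    find_base_4,
    find_initial_base,
    iter_bases_3plus1,
    place_atom_rugb,
    place_atom_ugb,
    ranked_bases_3plus1,
    solve,
)
from geobuild.synthetic import GeneratorConfig, generate_solvable_instance, generate_structure

from conftest import random_nondegenerate_base


def cloud_instance(rng, n=10, cutoff=1e9):
    coords = rng.uniform(0, 6, (n, 3))
    s = Structure(coords=coords)
    d = build_distance_set(s, cutoff)
    return s, d, build_adjacency_index(d)


def path_distance_set(n=8):
    d = SparseDistanceSet(n=n)
    for i in range(n - 1):
        d.add(i, i + 1, 1.5)
    return d


class TestInitialBase:
    def test_complete_graph_first_clique(self, rng):
        _, d, idx = cloud_instance(rng)
        base = find_initial_base(idx, d)
        assert base.base_ids == (0, 1, 2, 3)
        assert not is_degenerate(base.base_coords)

    def test_path_graph_has_no_clique(self):
        d = path_distance_set()
        with pytest.raises(NoInitialBase):
            find_initial_base(build_adjacency_index(d), d)

    def test_start_hint_advances_deterministically(self, rng):
        _, d, idx = cloud_instance(rng)
        b0 = find_initial_base(idx, d, start_hint=0)
        b1 = find_initial_base(idx, d, start_hint=1)
        assert b0.base_ids != b1.base_ids
        assert find_initial_base(idx, d, start_hint=0).base_ids == b0.base_ids

    def test_clique_distances_all_present(self):
        s, d, _ = (None, None, None)
        structure, dset, _cut = generate_solvable_instance(
            GeneratorConfig(n=60, seed=3)
        )
        idx = build_adjacency_index(dset)
        base = find_initial_base(idx, dset)
        for i, j in combinations(base.base_ids, 2):
            assert dset.get(i, j) is not None


class TestBaseSearch:
    def test_four_positioned_neighbours_found(self, rng):
        s, d, idx = cloud_instance(rng, n=6)
        positioned = np.array([True] * 5 + [False])
        base = find_base_4(5, idx, positioned, s.coords, d)
        assert base is not None and len(base.base_ids) == 4

    def test_three_positioned_neighbours_insufficient(self, rng):
        s, d, idx = cloud_instance(rng, n=6)
        positioned = np.array([True, True, True, False, False, False])
        assert find_base_4(5, idx, positioned, s.coords, d) is None

    def test_only_noncoplanar_subset_selected(self, rng):
        # five positioned neighbours, four of them coplanar
        coords = np.array(
            [
                [0.0, 0, 0], [1.0, 0, 0], [0.0, 1, 0], [1.0, 1, 0],  # plane z=0
                [0.5, 0.5, 1.0],  # off-plane
                [0.5, 0.5, 3.0],  # the atom to place
            ]
        )
        s = Structure(coords=coords)
        d = build_distance_set(s, 1e9)
        idx = build_adjacency_index(d)
        positioned = np.array([True] * 5 + [False])
        base = find_base_4(5, idx, positioned, coords, d)
        assert 4 in base.base_ids  # any valid base must use the off-plane atom
        # oracle: every returned base must match some non-degenerate 4-subset
        valid = [
            q for q in combinations(range(5), 4)
            if not is_degenerate(coords[list(q)])
        ]
        assert base.base_ids in valid

    def test_3plus1_base_matches_exhaustive_search(self, rng):
        structure, dset, _ = generate_solvable_instance(GeneratorConfig(n=50, seed=5))
        idx = build_adjacency_index(dset)
        positioned = np.zeros(50, dtype=bool)
        positioned[:30] = True
        coords = structure.coords
        for atom in range(30, 50):
            got = find_base_3plus1(atom, idx, positioned, coords, dset)
            # brute-force oracle over the atom's neighbour array
            nbrs = [j for j, _ in idx.neighbours[atom] if positioned[j]]
            expected = None
            for tri in combinations(nbrs, 3):
                if any(dset.get(a, b) is None for a, b in combinations(tri, 2)):
                    continue
                if is_degenerate(coords[list(tri)]):
                    continue
                for x in nbrs:
                    if x in tri:
                        continue
                    if not is_degenerate(np.vstack([coords[list(tri)], coords[x]])):
                        expected = (tri, x)
                        break
                if expected:
                    break
            if expected is None:
                assert got is None
            else:
                assert got is not None
                assert (got.base_ids, got.extra_id) == expected

    def test_all_coplanar_neighbours_give_no_3plus1_base(self):
        coords = np.array(
            [[0.0, 0, 0], [2.0, 0, 0], [1.0, 2, 0], [1.0, -2, 0], [1.0, 0.5, 3.0]]
        )
        s = Structure(coords=coords)
        d = build_distance_set(s, 1e9)
        idx = build_adjacency_index(d)
        positioned = np.array([True, True, True, True, False])
        assert find_base_3plus1(4, idx, positioned, coords, d) is None

    def test_rugb_search_touches_only_the_atoms_neighbour_array(self, rng):
        structure, dset, _ = generate_solvable_instance(GeneratorConfig(n=40, seed=9))
        idx = build_adjacency_index(dset)
        positioned = np.ones(40, dtype=bool)
        positioned[35:] = False
        adj = [set(idx.neighbour_ids(i)) for i in range(40)]

        accessed = []

        class SpyList(list):
            def __getitem__(self, i):
                accessed.append(i)
                return super().__getitem__(i)

        idx.neighbours = SpyList(idx.neighbours)
        ranked_bases_3plus1(36, idx, positioned, structure.coords, dset, adj)
        assert set(accessed) == {36}


class TestPlacementKernels:
    def _clique_instance(self, rng, n=12):
        coords = random_nondegenerate_base(rng, k=4)
        extra = rng.uniform(-4, 4, (n - 4, 3))
        s = Structure(coords=np.vstack([coords, extra]))
        d = build_distance_set(s, 1e9)
        return s, d

    def test_ugb_placement_restores_original_distances_under_noise(self, rng):
        s, d = self._clique_instance(rng)
        atom, ids = 7, (0, 1, 2, 3)
        noisy = s.coords[list(ids)] + rng.normal(0, 1e-6, (4, 3))
        base = MetricBase(base_ids=ids, base_coords=noisy)
        out = place_atom_ugb(atom, base, d, tol=1e-3)
        # all 10 pairwise distances within the 5-atom complex match originals
        full = np.vstack([out[:4], out[4]])
        ref_ids = list(ids) + [atom]
        for a, b in combinations(range(5), 2):
            want = d.get(ref_ids[a], ref_ids[b])
            got = np.linalg.norm(full[a] - full[b])
            assert abs(got - want) < 1e-9

    def test_ugb_placement_idempotent_on_exact_base(self, rng):
        s, d = self._clique_instance(rng)
        atom, ids = 9, (0, 1, 2, 3)
        base = MetricBase(base_ids=ids, base_coords=s.coords[list(ids)])
        out = place_atom_ugb(atom, base, d)
        assert np.abs(out[:4] - s.coords[list(ids)]).max() < 1e-10
        assert np.linalg.norm(out[4] - s.coords[atom]) < 1e-9

    def test_rugb_placement_reproduces_all_four_distances(self, rng):
        s, d = self._clique_instance(rng)
        atom, tri, extra = 8, (0, 1, 2), 3
        base = MetricBase(
            base_ids=tri, base_coords=s.coords[list(tri)], extra_id=extra
        )
        out = place_atom_rugb(atom, base, s.coords[extra], d)
        for k, b in enumerate(tri):
            assert abs(np.linalg.norm(out[3] - out[k]) - d.get(atom, b)) < 1e-10
        assert abs(
            np.linalg.norm(out[3] - s.coords[extra]) - d.get(atom, extra)
        ) < 1e-9

    def test_rugb_mirror_trap_rejected(self):
        # extra atom deliberately in the base plane: candidates equidistant
        coords = np.array(
            [
                [0.0, 0, 0], [2.0, 0, 0], [1.0, 1.8, 0],  # base triangle (z=0)
                [4.0, -1.0, 0.0],  # coplanar "extra"
                [1.0, 0.6, 1.3],  # true position of the atom to place
            ]
        )
        s = Structure(coords=coords)
        d = build_distance_set(s, 1e9)
        base = MetricBase(
            base_ids=(0, 1, 2), base_coords=coords[:3], extra_id=3
        )
        with pytest.raises(AmbiguousPlacement):
            place_atom_rugb(4, base, coords[3], d)

    def test_rugb_and_ugb_agree_where_both_bases_exist(self, rng):
        s, d = self._clique_instance(rng, n=10)
        atom = 6
        base4 = MetricBase(base_ids=(0, 1, 2, 3), base_coords=s.coords[:4])
        base3 = MetricBase(
            base_ids=(0, 1, 2), base_coords=s.coords[:3], extra_id=3
        )
        out_u = place_atom_ugb(atom, base4, d)
        out_r = place_atom_rugb(atom, base3, s.coords[3], d)
        assert np.linalg.norm(out_u[4] - out_r[3]) < 1e-8


class TestSolve:
    @pytest.mark.parametrize("algorithm", ["gb", "ugb", "rugb"])
    def test_complete_data_reconstruction_is_exact(self, algorithm, rng):
        coords = rng.uniform(0, 8, (50, 3))
        s = Structure(coords=coords)
        d = build_distance_set(s, 1e9)
        result = solve(d, SolverOptions(algorithm=algorithm))
        assert result.status == "complete"
        err, _ = aligned_rmsd(result.structure.coords, coords)
        assert err < 1e-8

    def test_path_graph_fails(self):
        result = solve(path_distance_set(), SolverOptions(algorithm="rugb"))
        assert result.status == "failed"

    def test_sparse_chain_rugb_completes_accurately(self):
        s, d, _ = generate_solvable_instance(GeneratorConfig(n=120, seed=11))
        result = solve(d, SolverOptions(algorithm="rugb"))
        assert result.status == "complete"
        err, _ = aligned_rmsd(result.structure.coords, s.coords)
        assert err < 1e-6

    @pytest.mark.parametrize("algorithm", ["ugb", "rugb"])
    def test_updating_algorithms_respect_input_distances(self, algorithm):
        s, d, _ = generate_solvable_instance(GeneratorConfig(n=150, seed=21))
        result = solve(d, SolverOptions(algorithm=algorithm))
        assert result.status == "complete"
        assert max_distance_violation(result, d) < 1e-6

    def test_provenance_recorded_for_every_placed_atom(self):
        s, d, _ = generate_solvable_instance(GeneratorConfig(n=80, seed=13))
        result = solve(d, SolverOptions(algorithm="rugb"))
        placed = set(result.positioned_ids()) - set(result.initial_base)
        assert placed == set(result.provenance)

    def test_solver_is_deterministic(self):
        _, d, _ = generate_solvable_instance(GeneratorConfig(n=80, seed=17))
        r1 = solve(d, SolverOptions(algorithm="rugb"))
        r2 = solve(d, SolverOptions(algorithm="rugb"))
        assert (r1.structure.coords == r2.structure.coords).all()

    def test_explicit_initial_base_is_used(self, rng):
        coords = rng.uniform(0, 8, (30, 3))
        d = build_distance_set(Structure(coords=coords), 1e9)
        result = solve(
            d, SolverOptions(algorithm="ugb", initial_base=(5, 9, 12, 20))
        )
        assert result.initial_base == (5, 9, 12, 20)
        assert result.status == "complete"
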