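# Methods

## Problem and assumptions

The solvers address the molecular distance geometry problem restricted
to *exact* distances: every supplied d<sub>ij</sub> is assumed to be the
true Euclidean distance to full double precision.  There is no handling
of measurement noise or distance intervals (upper/lower bounds); all
tolerances below exist to absorb floating-point round-off only.
Distances are in ångström throughout.

A sparse instance is a graph on n atoms whose edges carry distances.
Build-up solvability is a graph-plus-geometry property: the solvers need
an initial 4-clique that embeds as a non-degenerate tetrahedron, and
every remaining atom must eventually acquire enough positioned
references.  Reconstruction is unique only up to a rigid motion and a
global reflection, so accuracy is always reported as RMSD after optimal
superposition, minimized over both enantiomers (`aligned_rmsd`, which
also reports which mirror image was built).

## Placement kernels

* `trilaterate4`: squaring the four sphere equations and subtracting the
  first yields the linear system with rows 2(x<sub>i</sub> −
  x<sub>1</sub>)ᵀ, solved directly; residuals against all four input
  distances are checked afterwards.
* `trilaterate3`: the base triangle is mapped to a canonical planar
  frame, the in-plane coordinates (u, v) are solved in closed form and
  the out-of-plane offset is w = ±√(d₁² − u² − v²); tiny negative
  radicands (round-off on in-plane targets) are clamped to zero, larger
  ones raise `NoIntersection`.
* `disambiguate` picks the mirror candidate whose distance to a fourth,
  off-plane reference matches; it refuses (i) bases where both
  candidates match within tolerance yet differ by more than it
  (`AmbiguousPlacement` — a near-coplanar reference), and (ii) bases
  where neither matches (`InconsistentDistances`).
* Local frames (`init_triangle`, `init_tetrahedron`) use a fixed
  orientation convention — atom 1 at the origin, atom 2 on +x, atom 3 in
  the xy-plane with y ≥ 0, atom 4 with z ≥ 0 — so identical inputs give
  bit-identical outputs.  Realizability of a tetrahedron is checked
  constructively: the squared height of atom 4 may be no more negative
  than round-off (relative window 1e-8 of the squared scale) before it
  is clamped.

Degeneracy is always tested scale-invariantly: a 4-point base is flat
when |det of edge vectors| ≤ rel_tol × (product of edge norms), a
3-point base when the analogous cross-product test fails, with
rel_tol = 1e-8 by default.  Exact inputs make this window narrow; it
exists because near-flat bases amplify placement error sharply.

## The updating step

UGB rebuilds the 4-clique base from its six original distances in the
canonical frame, trilaterates the atom there from its four original
distances, and maps the five fresh atoms back with the least-squares
rigid fit (centering both point sets, C = Y₁ᵀX₁, Q = UVᵀ from the SVD).
Q is deliberately allowed to be improper (det −1): the fresh canonical
tetrahedron may be the mirror image of the placed one, and only an
improper Q maps it onto the old base.  The global chirality is anchored
by the initial base and resolved at evaluation time; for the 3-atom RUGB
base a proper rotation always suffices.

RUGB rebuilds the 3-clique base, computes both mirror candidates
locally, maps base + both candidates back, and disambiguates with the
extra atom's current position and original distance.  The chosen
position is then *polished* by up to two damped Gauss–Newton
least-squares steps against all four original reference distances
(three base atoms + extra atom).  Rationale: the mirror-candidate
construction satisfies only the three base distances, leaving the whole
residual of the fourth, equally exact distance on the extra atom;
distributing it over four references measurably reduces the error handed
to later placements, and the fourth atom is part of the metric base in
the uniqueness sense.  The polish is restricted to round-off scale: a
step larger than 10⁻³ × the consistency tolerance indicates genuinely
inconsistent reference coordinates (e.g. deliberately perturbed input),
and is skipped so that updated placements always reproduce the original
base distances.

Both updating placements replace the stored base coordinates with the
refreshed ones ("re-initialization"), which is what stops error
accumulation: every base a later atom uses has exact internal geometry.

## Base search and conditioning

Candidate enumeration is deterministic: neighbour triples/quadruples in
lexicographic order, initial 4-cliques in lexicographic order of the
sorted id tuple (successive restarts draw successive cliques,
`max_restarts` = 25 by default).  The op-level searches
(`find_base_4`, `find_base_3plus1`) return the first valid candidate in
that order.

The solver itself does not *place* from the first valid base.  Flat
bases amplify round-off — a thin base triangle tilts the re-insertion
fit, and a target atom far out of the base plane magnifies that tilt —
and with first-found selection the error of the 3+1 scheme was observed
to grow exponentially along the build order (reaching ~10⁻⁵ Å at
n = 300 from exact inputs).  The solver therefore ranks the enumerated
candidates by a scale-invariant conditioning score and tries the best
first:

* 4-atom bases: |det of edge vectors| / product of edge norms of the
  current coordinates (normalized tetrahedron volume);
* 3+1 bases: the worst of the triangle's normalized cross product and
  the extra atom's normalized out-of-plane height, where the extra atom
  is chosen to maximize that height.  Bases whose mirror candidates are
  neither clearly separable by the extra atom's distance (projected gap
  > 4× the consistency tolerance) nor effectively coincident are dropped
  up front — they would be rejected as ambiguous at placement time.

Ranking is applied to the leading `base_pool` (16) candidates for 3+1
bases and to the best `base_pool` of up to `max_base_candidates` (5000)
enumerated quadruples; the cap bounds pathological enumeration in very
dense neighbourhoods (complete-data instances) where the first few
candidates are already excellent.  All scores are computed from data the
algorithms legitimately hold (current coordinates and original
distances), and the ranking is a stable sort, so runs remain exactly
reproducible.  The same policy is applied to all three algorithms so
that accuracy differences between them reflect the updating scheme, not
the search.

When an atom has no all-original-distance base but does have four
positioned, non-coplanar neighbours, UGB and RUGB fall back to plain
(non-updated) trilateration; such placements are flagged in the per-atom
provenance.  GB's trilateration residual check is disabled — growing
residuals are the phenomenon it exhibits, measured at evaluation time as
`max_distance_violation`.

## Outer loop

Sweeps process unpositioned atoms in ascending id; a sweep that places
no atom ends the attempt.  A stalled attempt restarts from the next
initial clique (the initial base is not guaranteed to reach every atom);
the best partial result over all attempts is returned with per-atom
provenance (base, sweep, restart, updated-or-fallback) and counts.

## Synthetic instances

`synthetic` generates the study inputs without any downloads:

* **chain** mode (default): a self-avoiding persistent random walk with
  bond length 1.5 Å (a generic covalent bond), excluded volume 1.0 Å and
  Gaussian direction jitter 0.9, emulating a compact polypeptide
  heavy-atom trace.  Consecutive atoms are exactly bond-length apart, so
  a 5 Å-scale cutoff graph always contains the short-range contacts NMR
  would see plus fold-back contacts.
* **cloud** mode: uniform points in a cube at 0.05 atoms/Å³ (protein
  interior packing density), rejection-sampled for the 1.0 Å minimum
  separation.

`generate_solvable_instance` certifies an instance by a purely
combinatorial dry run of the relaxed base-existence condition (initial
4-clique, then repeatedly: three mutually-adjacent positioned neighbours
plus any fourth positioned neighbour), growing the cutoff by 10 % steps
(bounded) when certification fails.  At n = 300 the 5 Å request
typically certifies at 6.05 Å with ~2300 pairs and d_max/n ≈ 0.1–0.2,
the same sparsity regime as all-atom protein cutoff graphs.  The
certification is graph-only; geometric degeneracies are left to runtime
and surface as restarts.  What these instances do *not* model: real
covalent geometry (bond angles, rings, side chains), heteroatom
composition, and any distance noise — so passing tests demonstrate
correctness of the reconstruction machinery on exact data, not
robustness to experimental error.

## Study sizes

The test suite and `scripts/acceptance.py` use: 1,000 random instances
for the trilateration-vs-oracle comparison; a 200-atom cloud with
complete distances for the exactness check; 20 chain instances of 300
atoms for the sparse comparison; and ~50 noisy placements for the
noise-injection check.  These sizes keep a full run in the minutes range
on one core while matching the protein scale of typical applications.

## Observed behaviour

On the sparse study, both updating algorithms complete every certified
instance with aligned RMSD around 10⁻¹²–10⁻¹⁰ Å (RUGB's median at or
slightly below UGB's), while plain GB either stalls or produces
structures wrong by many orders of magnitude — the motivating
observation for updating.  All numbers are recomputed at run time by the
acceptance script.

## Limitations

* Exact distances only; no intervals, no noise model.
* PDB reading selects one model with a fixed altloc policy ('' or 'A');
  mmCIF and assembly expansion are out of scope.
* Pair generation is O(n²); fine for n up to a few thousand, no spatial
  index is used.
* Wall-clock performance is logged but not benchmarked; the complexity
  bounds of the neighbour-array search are documented, not asserted.
* A 4-clique-free graph (e.g. a path) is unsolvable by construction and
  is reported as `failed`.
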