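# Methods

## Problem setting

Molecular surface meshes — triangulations of a smooth implicit surface
around a set of atoms — are consumed by boundary-element and
finite-element solvers for implicit-solvent electrostatics and by
tetrahedral mesh generators.  Both require a closed, edge-manifold,
self-intersection-free mesh with bounded triangle angles.  Raw surfacer
output violates all of this: near-zero-degree slivers, redundant
(duplicate or over-dense) vertices, and narrow bridges of tiny triangles
connecting different sheets of the surface.

`molremesh` refines such meshes to the angle bound [30°, 120°].  The two
bounds are one constraint: a triangle with an angle above 120° necessarily
has one below 30° (angles sum to 180°), so "no angle below 30°" implies
both.

## Quality metrics

For a triangle t with side lengths a, b, c, half-perimeter S = p,
longest edge h, and area A:

* quality Q(t) = (6/√3)·A/(p·h) ∈ [0, 1], 1 exactly for equilateral;
* aspect ratio AR(t) = abc / (8(S−a)(S−b)(S−c)) ≥ 1, 1 exactly for
  equilateral, undefined for degenerate triangles;
* vertex aspect ratio ARv = mean AR over the faces incident to v.

A triangle is *degenerate* when A < 10⁻¹²·h².  Degenerate triangles have
Q = 0 and an undefined AR, represented as `inf`, which deliberately
compares worse than every finite value so any move away from degeneracy
counts as an improvement.  Reports serialize it as `"undef."`.

Topology: Euler number E = n_v + n_f − n_e and genus = 1 − E/2 for closed
surfaces (internal cavities drive the genus negative).  Regular vertices
are those with valence 5–7 (interior) or 3–5 (boundary).  Enclosed volume
is the absolute signed-tetrahedron sum, so inverted orientation is
tolerated.  Self-intersections are unordered pairs of faces sharing no
vertex whose closed triangles intersect; detection uses a uniform spatial
hash over face boxes with an exact Möller-style narrow phase (coplanar
overlap through 2-D polygon intersection), and an O(n²) all-pairs variant
serves as an independent oracle at desk scale.

## Pipeline stages

**Initialization.** Discrete curvatures use the cotangent Laplacian with
mixed Voronoi areas (H = ‖Δv‖/2) and the angle deficit
K = (2π − Σθ)/A_mixed; κ = H + √(max(H²−K, 0)).  The sizing field
L(v) = √(max(6ε/κ − 3ε², 0)) is clamped to [0.1, 3]× the input mean edge
length (the formula diverges as κ → 0) and graded by two neighbor-average
sweeps — raw meshes have spiky curvature at defects, and an ungraded
field freezes tiny target lengths in place, blocking the very collapses
that remove slivers.  ε defaults to 0.002× the bounding-box diagonal.
Each of 5 iterations runs: split edges > (4/3)L, flip, collapse edges
< (4/5)L (link condition, no over-long new edges, no normal flips),
flip, then three sweeps of tangential Laplacian relaxation with
projection to the reference surface.  Flips require a strict decrease of
the squared valence deviation from 6.

**Reference surface.** All projection steps target the input mesh with
its narrow regions removed.  Narrow bridges are artifacts the method is
designed to delete; keeping them in the projection target drags refilled
patches into the interior.  Closest-point queries use a k-NN candidate
search over triangle centroids with an exact fallback whenever the
candidate set cannot certify the optimum; oversized triangles (the
bridges) are tested exhaustively so they cannot break the certification
bound.  Projected positions that land more than twice the local edge
length from the query are distrusted and skipped (deep holes otherwise
snap onto the wrong sheet).

**Aspect-ratio improvement.** Candidates per vertex, in order: the mixed
Voronoi cell centroid (circumcenter subcells for non-obtuse incident
triangles, barycentric fallback otherwise, projected to the tangent
plane), then the one-ring Laplacian center.  A candidate is first
projected to the reference, then accepted only if (a) ARv strictly
decreases, (b) no incident finite AR becomes undefined, (c) the
valence-weighted sum of finite incident ARs does not increase, and
(d) no incident face normal flips.  Guard (c) makes the pass-level
invariant — mean finite ARv never increases — an exact theorem rather
than a tendency.  Three passes by default.  Candidates are computed from
the pass-start geometry and acceptance is evaluated sequentially against
live positions (Jacobi candidates, Gauss–Seidel acceptance); this keeps
the guarantee while allowing batch projection.

**Cut-and-fill.** Faces with an angle strictly below the round threshold
are small; invalid regions are the one-ring dilations of their vertices,
split into edge-connected components.  Narrow regions are components of
small faces whose removal opens ≥ 2 boundary loops (bridge topology) and
are removed whole.  Hole boundaries are walked with fan rotation, so
pinched vertices are handled; each loop is oriented for filling and
carries ē, the mean edge length of adjacent kept triangles, fixed at cut
time.

Filling is an advancing front over the boundary queue: connect vertex i
to i+2 (an ear over i+1) unless the ear's minimum angle is below 15° or
the ear crosses nearby geometry.  The front keeps a moving cursor — each
accepted ear continues from its own position — because restarting at the
queue head grows high-valence fans.  When a full lap places no ear, a
new vertex is inserted at the loop centroid (projected, snap-capped) and
attached where its triangle clears the intersection guard.  Stalls with
an unchanged loop fall through to a force-fill that takes the best
available ear (non-crossing ears strictly preferred); such sub-15° faces
are deliberately left for the next cut round.  A hole that mirrors a
single existing triangle (a flap) is resolved by deleting the flap
rather than capping it, which would create a degenerate two-face pillow.
After triangulation, each newly created edge longer than 0.7·ē is split
once at its midpoint (children are not revisited; repeated halving
cascades).

**Local smoothing** of filled patches, in order: one guarded sweep
collapsing edges with an opposite angle < 30° (smallest first; link
condition, no normal flips, no intersection, and the local minimum angle
may not decrease), one sweep splitting edges with an opposite angle
> 90° at the obtuse vertex's projection onto the edge (skipped when the
foot falls outside the open segment — splitting there cannot cure the
corner), Lawson-style flips of patch-interior edges that strictly raise
the local minimum angle, then stochastic relocation.  The flips are an
addition to the collapse/split/relocate operator set: an advancing-front
fill can leave hub vertices of valence k whose minimum incident angle is
capped near 360°/k, so the 30° bound is topologically out of reach for
relocation alone.

Relocation draws, for each patch vertex and each step δ of the schedule
1, 1/2, 1/4, 1/6, 1/8, … (stopping below ε = 0.01), m = 8 random unit
directions in the tangent plane and tests v_f = c + k·δ·ℓ̄ (c the
Laplacian center, ℓ̄ the local mean edge length).  A candidate is
projected to the reference first and accepted only if the minimum angle
over the vertex's incident faces strictly increases, the minimum over
its incident *patch* faces does not decrease (needed for exact per-patch
monotonicity at patch boundaries), no incident normal flips, and no
intersection is created.  All randomness flows from the schedule seed;
runs are reproducible.

Intersection guards during smoothing collect the faces near a patch once
(boxes inflated well beyond the largest plausible relocation, narrow
phase always on live coordinates).  Guards skip only shared-edge pairs;
a pair sharing one vertex is still tested, because folds pass exactly
through shared vertices — the exact predicate's tolerance separates
point contact from genuine penetration.

**Second round and retries.** The cut/fill/smooth trio repeats at 30°.
If the result still has sub-30° angles or self-intersections, the trio
is repeated — from the best state seen so far, with fresh seeds — up to
10 times (stochastic restarts; a bad random round cannot compound).
The run fails loudly, carrying the best mesh and report, if the budget
is exhausted.

**Surface repair** welds duplicate vertices (tolerance 10⁻⁶× the
bounding-box diagonal; welds that would break edge-manifoldness are
skipped) and removes self-intersections by excising each crossing pair
plus one-rings and refilling, up to 5 rounds.  Repair uses a short
relocation schedule (δ ∈ {1/2, 1/4, 1/8}, 4 directions): its job is
seating patches, not angle polish, which belongs to the smoothing
rounds.  The best (fewest-crossings) round is kept.

## Synthetic fixtures

The generator replaces external surfacer output.  The Gaussian surface
is the level set {Σᵢ exp(−d(‖x−xᵢ‖² − rᵢ²)) = c} of a toy atom set,
extracted by marching cubes on a uniform grid with padding
max(2/√d, 2 Å).  The default atom set is a tetrahedral cluster of four
atoms (radii 1.5–2.0 Å) plus a center atom, with d = 0.5 and c = 1.0,
chosen so the surface fuses into a single smooth component with concave
necks — the geometry molecular surfaces actually have.  Defects are then
injected deterministically: a fraction of faces get an edge split next
to an endpoint (sub-degree slivers), a fraction get a barycentric 1-to-3
split (redundant valence-3 vertices), and narrow bridges are welded
between distant faces as thin tubes of tiny triangles (changing the
genus by +1 each, and self-intersecting the surface as raw bridges do).

What the fixtures do not emulate: the 10⁵-face scale of real surfacer
output, chemically meaningful radii/charges, deep cavities and tunnels
of real proteins, and surfacer-specific artifact statistics.  Passing
tests therefore demonstrate the operators' correctness and the angle
bound on realistic desk-scale geometry, not performance parity on
protein-scale data.

## Problem sizes and tolerances

The test suite and the acceptance script run the pipeline on fixtures at
marching-cubes resolutions 1.5 and 3.0 voxels/Å (≈1.5k and ≈6k raw
faces); these are the package's desk-scale study conditions.  Numerical
tolerances: angle sums hold to 10⁻⁶ degrees; metric invariances to 10⁻⁸
relative; the degenerate-triangle cutoff is area < 10⁻¹²·h²; the exact
intersection predicate treats contact within 10⁻⁹ of the local scale as
non-penetrating.  Determinism: identical inputs, configuration, and
seeds give identical outputs; hole and region traversal orders are fixed
by lowest vertex id.

## Known limitations

* The advancing-front force-fill can, on pathological interpenetrating
  hole boundaries, place sub-15° or crossing faces; these are handled by
  later rounds, but convergence of the retry loop is stochastic, not
  guaranteed.
* Geometric predicates are floating point with tolerances, not exact
  arithmetic.
* The angle bound is a property of the final report, not a per-operator
  invariant; intermediate meshes may be temporarily worse.
* Curvature estimates on heavily degraded one-rings are substituted by
  neighbor averages, which is a heuristic.
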