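"""Surface repair: duplicate-vertex welding and self-intersection removal.

Residual defects after the main refinement rounds — coincident vertices
left by the raw surfacer and any remaining pairs of crossing triangles —
are removed here so that downstream volume meshing (tetrahedralization)
preconditions hold.  Self-intersections are excised with the same
cut-and-fill machinery used for invalid regions: both faces of every
intersecting pair plus their one-rings are removed, the holes refilled,
and the patches locally smoothed; this repeats until the intersection
count reaches zero or the round budget is exhausted.
"""
from __future__ import annotations

import logging
import math

import numpy as np
from scipy.spatial import cKDTree

from ._edit import EditableMesh
from .cut_fill import RegionSelection, _cut_em, _fill_em
from .errors import RepairIncompleteError
from .local_smooth import (
    SmoothingSchedule,
    _collapse_short_em,
    _flip_improve_em,
    _optimize_vertex,
    _ProximityGuard,
    _region_edges,
    _split_long_em,
)
from .mesh_core import TriangleMesh, self_intersections
from ._geometry import MeshProjector

__all__ = ["merge_duplicate_vertices", "surface_repair"]

log = logging.getLogger("molremesh")


def merge_duplicate_vertices(mesh: TriangleMesh, tol: float) -> TriangleMesh:
    """Weld vertices closer than ``tol`` (A); faces that become degenerate
    (repeated indices) are dropped, as are back-to-back duplicate face
    pairs.  A weld whose outcome would not be edge-manifold is skipped.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    if tol == 0 or mesh.n_vertices == 0:
        return mesh
    tree = cKDTree(mesh.vertices)
    pairs = tree.query_pairs(tol)
    if not pairs:
        return mesh

    parent = list(range(mesh.n_vertices))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in sorted(pairs):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    clusters: dict[int, list[int]] = {}
    for v in range(mesh.n_vertices):
        clusters.setdefault(find(v), []).append(v)
    weld_clusters = sorted(c for c in clusters.values() if len(c) > 1)

    def apply_welds(active: list[list[int]]):
        remap = np.arange(mesh.n_vertices)
        newpos = mesh.vertices.copy()
        for members in active:
            root = members[0]
            remap[members] = root
            newpos[root] = mesh.vertices[members].mean(axis=0)
        F = remap[mesh.faces]
        keep = ~((F[:, 0] == F[:, 1]) | (F[:, 1] == F[:, 2]) | (F[:, 0] == F[:, 2]))
        F = F[keep]
        # drop duplicate-vertex-set faces: both of a back-to-back pair
        # (zero-volume flap), the extras of a same-orientation stack
        key = np.sort(F, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        F = F[counts[inv] == 1]
        return TriangleMesh(newpos, F, validate=False)

    candidate = apply_welds(weld_clusters)
    if candidate.is_edge_manifold:
        out = candidate
    else:
        # retry skipping the clusters whose weld breaks manifoldness
        good: list[list[int]] = []
        for c in weld_clusters:
            trial = apply_welds(good + [c])
            if trial.is_edge_manifold:
                good.append(c)
            else:
                log.info("merge_duplicate_vertices: skipped weld of %s", c)
        out = apply_welds(good)

    # compact away now-unreferenced vertices
    used = np.zeros(out.n_vertices, dtype=bool)
    if out.n_faces:
        used[out.faces.ravel()] = True
    index = np.cumsum(used) - 1
    return TriangleMesh(out.vertices[used], index[out.faces], validate=False)


def surface_repair(mesh: TriangleMesh, max_rounds: int = 5,
                   schedule: SmoothingSchedule | None = None,
                   reference: TriangleMesh | None = None,
                   raise_on_failure: bool = True) -> TriangleMesh:
    """Excise-and-refill removal of self-intersections (plus duplicate
    welding).  Raises RepairIncompleteError when intersections survive
    ``max_rounds`` rounds (or returns the best round's mesh when
    ``raise_on_failure`` is False, e.g. inside pipeline retries)."""
    if schedule is None:
        schedule = SmoothingSchedule()
    # repair only needs enough relocation to seat the refilled patches;
    # the full descending schedule is the angle-polishing tool of the
    # smoothing stage, and a short one keeps repair rounds cheap
    schedule = SmoothingSchedule(
        epsilon=0.1, deltas=(0.5, 0.25, 0.125),
        directions_per_step=min(4, schedule.directions_per_step),
        seed=schedule.seed,
    )
    bbox = mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0) if mesh.n_vertices else np.ones(3)
    mesh = merge_duplicate_vertices(mesh, 1e-6 * float(np.linalg.norm(bbox)))

    projector = None
    if reference is not None:
        projector = MeshProjector(reference.vertices, reference.faces)

    prev = None
    best_mesh, best_count = mesh, None
    for round_no in range(max_rounds):
        pairs = self_intersections(mesh)
        log.info("surface_repair round %d: %d intersecting pairs", round_no, len(pairs))
        if not pairs:
            return mesh
        if best_count is None or len(pairs) < best_count:
            best_mesh, best_count = mesh, len(pairs)
        if prev is not None and len(pairs) > prev:
            log.warning(
                "surface_repair: intersection count rose from %d to %d", prev, len(pairs)
            )
        prev = len(pairs)

        bad_faces: set[int] = set()
        for p in pairs:
            bad_faces.add(p.face_a)
            bad_faces.add(p.face_b)
        vfaces = mesh.vertex_faces
        region: set[int] = set()
        for fi in bad_faces:
            for v in mesh.faces[fi]:
                region.update(vfaces[int(v)])
        if len(region) > max(0.1 * mesh.n_faces, 100):
            # the excision region has grown past any plausible defect
            # cluster: this round is diverging, keep the best state
            log.warning("surface_repair: region of %d faces too large, stopping",
                        len(region))
            break

        em = EditableMesh.from_mesh(mesh)
        holes = _cut_em(em, region)
        patches = [_fill_em(em, h, projector) for h in holes]
        for patch in patches:
            patch.faces &= set(em.F)
            patch.vertices &= set(em.V)
            if not patch.faces:
                continue
            verts0 = set(patch.vertices)
            for fid in patch.faces:
                verts0.update(em.F[fid])
            margin = 1.5 * float(np.mean([
                em.edge_length(u, v) for u, v in _region_edges(em, patch.faces)
            ]))
            guard = _ProximityGuard(em, verts0, margin)
            _collapse_short_em(em, patch, guard)
            _split_long_em(em, patch)
            _flip_improve_em(em, patch, guard)
            rng = np.random.default_rng((schedule.seed + round_no) % (2**31))
            verts = set(patch.vertices)
            for fid in patch.faces:
                verts.update(em.F[fid])
            guard = _ProximityGuard(em, verts, margin)
            for vid in sorted(verts):
                if vid in em.V:
                    _optimize_vertex(em, vid, patch.faces, schedule, rng,
                                     projector, guard)
            _flip_improve_em(em, patch, guard)
        mesh, _, _ = em.to_mesh()

    pairs = self_intersections(mesh)
    if not pairs:
        return mesh
    if len(pairs) < (best_count if best_count is not None else math.inf):
        best_mesh, best_count = mesh, len(pairs)
    if raise_on_failure:
        raise RepairIncompleteError(len(pairs))
    log.warning("surface_repair: %d intersecting pairs remain (best round kept)",
                best_count)
    return best_mesh
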