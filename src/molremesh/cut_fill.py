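"""Cut-and-fill removal of invalid mesh regions.

Triangles with an angle below a threshold are *small* (invalid); the
one-ring neighborhoods of their vertices form the invalid regions.  A
connected component of small triangles whose excision opens two or more
boundary loops is a *narrow region* — the thin tube/bridge pathology —
and is removed whole, leaving one hole per side.  Every hole is refilled
by an advancing front over the boundary queue: vertex i is connected to
vertex i+2 (an ear over i+1) whenever the new triangle's minimum angle
is at least 15 degrees and it does not intersect nearby faces; when a
full lap over the queue places no ear, a new vertex is inserted at the
loop centroid (projected to the reference surface when one is given).
After filling, any newly created edge longer than 0.7 x the hole's mean
adjacent edge length is split at its midpoint.

The traversal order is fixed (holes by lowest vertex id, ears by queue
position), so identical inputs give identical outputs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _geometry as geom
from ._edit import EditableMesh
from ._geometry import MeshProjector
from .errors import InvalidHoleError
from .mesh_core import TriangleMesh

__all__ = [
    "RegionSelection",
    "HoleBoundary",
    "label_small_triangles",
    "invalid_regions",
    "detect_narrow_regions",
    "cut_regions",
    "fill_hole",
    "cut_and_fill",
]

FILL_MIN_ANGLE = 15.0  # degrees: ear rejection floor
SPLIT_FACTOR = 0.7     # new edges longer than 0.7 * mean adjacent edge split


@dataclass
class RegionSelection:
    """A set of faces (plus their vertices) marking an invalid region, a
    narrow region, or a freshly filled patch."""

    faces: set[int]
    vertices: set[int]
    kind: str = "invalid-region"


@dataclass
class HoleBoundary:
    """Ordered boundary loop of a hole.

    Consecutive loop vertices follow the orientation the filling faces
    must use (the reverse of the kept faces' traversal), so an ear
    (v_i, v_{i+1}, v_{i+2}) is consistently oriented.  ``mean_edge_length``
    is the average edge length of the kept triangles adjacent to the
    hole, fixed at cut time.
    """

    loop: list[int]
    mean_edge_length: float

    def __post_init__(self):
        if len(self.loop) < 3:
            raise InvalidHoleError(f"hole loop of length {len(self.loop)}")


# ---------------------------------------------------------------------------
# labeling
# ---------------------------------------------------------------------------

def label_small_triangles(mesh: TriangleMesh, theta_min: float) -> set[int]:
    """Faces whose minimum interior angle is strictly below ``theta_min``."""
    if not (0.0 < theta_min < 60.0):
        raise ValueError("theta_min must be in (0, 60) degrees")
    ang = geom.face_angles_deg(mesh.vertices, mesh.faces)
    if len(ang) == 0:
        return set()
    return set(np.nonzero(ang.min(axis=1) < theta_min)[0].tolist())


def _edge_connected_components(mesh: TriangleMesh, faces: set[int]) -> list[set[int]]:
    """Split a face set into components connected across shared edges."""
    if not faces:
        return []
    edge_map: dict[tuple[int, int], list[int]] = {}
    for fi in faces:
        a, b, c = (int(x) for x in mesh.faces[fi])
        for u, v in ((a, b), (b, c), (c, a)):
            e = (u, v) if u < v else (v, u)
            edge_map.setdefault(e, []).append(fi)
    parent = {fi: fi for fi in faces}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for group in edge_map.values():
        for other in group[1:]:
            ra, rb = find(group[0]), find(other)
            if ra != rb:
                parent[rb] = ra
    comps: dict[int, set[int]] = {}
    for fi in faces:
        comps.setdefault(find(fi), set()).add(fi)
    return sorted(comps.values(), key=min)


def _region_from_faces(mesh: TriangleMesh, faces: set[int], kind: str) -> RegionSelection:
    verts = {int(x) for fi in faces for x in mesh.faces[fi]}
    return RegionSelection(faces=set(faces), vertices=verts, kind=kind)


def invalid_regions(mesh: TriangleMesh, theta_min: float,
                    rings: int = 1) -> list[RegionSelection]:
    """One-ring dilations of the small triangles (``rings`` times), split
    into edge-connected components."""
    small = label_small_triangles(mesh, theta_min)
    if not small:
        return []
    vfaces = mesh.vertex_faces
    region_faces: set[int] = set(small)
    for _ in range(max(rings, 0)):
        grown = set(region_faces)
        for fi in region_faces:
            for v in mesh.faces[fi]:
                grown.update(vfaces[int(v)])
        region_faces = grown
    return [
        _region_from_faces(mesh, comp, "invalid-region")
        for comp in _edge_connected_components(mesh, region_faces)
    ]


def _boundary_loop_count(mesh: TriangleMesh, comp: set[int]) -> int:
    """Number of boundary curves the removal of ``comp`` would open,
    counted as connected components of the rim edges."""
    edge_map: dict[tuple[int, int], int] = {}
    for fi in comp:
        a, b, c = (int(x) for x in mesh.faces[fi])
        for u, v in ((a, b), (b, c), (c, a)):
            e = (u, v) if u < v else (v, u)
            edge_map[e] = edge_map.get(e, 0) + 1
    rim = [e for e, cnt in edge_map.items() if cnt == 1]
    if not rim:
        return 0
    import networkx as nx

    g = nx.Graph()
    g.add_edges_from(rim)
    return nx.number_connected_components(g)


def detect_narrow_regions(mesh: TriangleMesh, theta_min: float) -> list[RegionSelection]:
    """Connected components of small triangles forming bridges/tubes: their
    removal opens at least two boundary loops."""
    small = label_small_triangles(mesh, theta_min)
    out = []
    for comp in _edge_connected_components(mesh, small):
        if _boundary_loop_count(mesh, comp) >= 2:
            out.append(_region_from_faces(mesh, comp, "narrow-region"))
    return out


# ---------------------------------------------------------------------------
# cutting
# ---------------------------------------------------------------------------

def _next_hole_edge(em: EditableMesh, a: int, b: int) -> tuple[int, int]:
    """Follow the hole boundary from directed hole edge (a, b): rotate
    around b through the kept faces to the next boundary edge of the same
    fan (correct even at pinched vertices)."""
    f = None
    for fid in em.faces_of_edge(a, b):
        if em.directed_edge_in_face(fid, b, a):
            f = fid
            break
    if f is None:
        raise InvalidHoleError(f"inconsistent boundary at edge ({a}, {b})")
    w = em.opposite_vertex(f, a, b)
    seen = 0
    while True:
        nxt = [fid for fid in em.faces_of_edge(b, w) if fid != f]
        if not nxt:
            return (b, w)
        f = nxt[0]
        w = em.opposite_vertex(f, b, w)
        seen += 1
        if seen > 10000:
            raise InvalidHoleError(f"non-terminating fan walk at vertex {b}")


def _extract_hole_loops(em: EditableMesh) -> list[list[int]]:
    hole_edges: set[tuple[int, int]] = set()
    for u, v in em.boundary_edges():
        fid = em.faces_of_edge(u, v)[0]
        if em.directed_edge_in_face(fid, u, v):
            hole_edges.add((v, u))
        else:
            hole_edges.add((u, v))
    loops: list[list[int]] = []
    remaining = set(hole_edges)
    while remaining:
        start = min(remaining)
        loop = [start[0]]
        cur = start
        while True:
            remaining.discard(cur)
            nxt = _next_hole_edge(em, *cur)
            if nxt == start:
                break
            if nxt not in remaining:
                raise InvalidHoleError("boundary walk left the hole edge set")
            loop.append(nxt[0])
            cur = nxt
        loops.append(loop)
    return sorted(loops, key=min)


def _mean_adjacent_edge(em: EditableMesh, loop: list[int]) -> float:
    fids: set[int] = set()
    for v in loop:
        fids.update(em.vf.get(v, ()))
    lengths = []
    for fid in fids:
        a, b, c = em.F[fid]
        for u, v in ((a, b), (b, c), (c, a)):
            lengths.append(em.edge_length(u, v))
    return float(np.mean(lengths)) if lengths else 0.0


def _cut_em(em: EditableMesh, face_ids: set[int]) -> list[HoleBoundary]:
    touched: set[int] = set()
    for fid in sorted(face_ids):
        if fid in em.F:
            touched.update(em.F[fid])
            em.remove_face(fid)
    for vid in sorted(touched):
        em.remove_isolated_vertex(vid)
    return [
        HoleBoundary(loop=loop, mean_edge_length=_mean_adjacent_edge(em, loop))
        for loop in _extract_hole_loops(em)
    ]


def cut_regions(mesh: TriangleMesh, regions: list[RegionSelection]
                ) -> tuple[TriangleMesh, list[HoleBoundary]]:
    """Delete the regions' faces (and orphaned vertices); return the open
    mesh and one oriented HoleBoundary per resulting hole.

    Note the returned hole loops are indexed against the *returned* mesh.
    """
    em = EditableMesh.from_mesh(mesh)
    holes = _cut_em(em, {f for r in regions for f in r.faces})
    out, vid_map, _ = em.to_mesh()
    remapped = [
        HoleBoundary([vid_map[v] for v in h.loop], h.mean_edge_length)
        for h in holes
    ]
    return out, remapped


# ---------------------------------------------------------------------------
# filling
# ---------------------------------------------------------------------------

class _LocalGuard:
    """AABB-prefiltered intersection guard for candidate fill triangles.

    Screens against every face near the hole: faces incident to the loop
    plus any face whose bounding box overlaps the loop's box expanded by
    twice the hole's mean adjacent edge length.
    """

    def __init__(self, em: EditableMesh, loop: list[int], margin: float = 0.0):
        self.em = em
        self.fids: set[int] = set()
        for v in loop:
            self.fids.update(em.vf.get(v, ()))
        if margin > 0.0 and loop:
            pts = np.array([em.V[v] for v in loop if v in em.V])
            lo = pts.min(axis=0) - margin
            hi = pts.max(axis=0) + margin
            for fid, f in em.F.items():
                if fid in self.fids:
                    continue
                T = np.array([em.V[x] for x in f])
                if (T.max(axis=0) < lo).any() or (T.min(axis=0) > hi).any():
                    continue
                self.fids.add(fid)

    def add(self, fid: int) -> None:
        self.fids.add(fid)

    def remove(self, fid: int) -> None:
        self.fids.discard(fid)

    def intersects(self, tri_vids: tuple[int, int, int]) -> bool:
        em = self.em
        T = np.array([em.V[v] for v in tri_vids])
        lo = T.min(axis=0)
        hi = T.max(axis=0)
        vs = set(tri_vids)
        for fid in self.fids:
            if fid not in em.F:
                continue
            # faces sharing an edge are never obstacles; a single shared
            # vertex is fine — point contact is below the intersection
            # tolerance while a genuine fold-through is not
            if len(vs & set(em.F[fid])) >= 2:
                continue
            O = np.array(em.face_points(fid))
            if (O.max(axis=0) < lo).any() or (O.min(axis=0) > hi).any():
                continue
            if geom.tri_tri_intersect(T, O):
                return True
        return False


def _ear_min_angle(em: EditableMesh, a: int, b: int, c: int) -> float:
    return geom.min_angle_deg(tuple(em.V[a]), tuple(em.V[b]), tuple(em.V[c]))


def _fill_em(em: EditableMesh, hole: HoleBoundary,
             projector: MeshProjector | None = None) -> RegionSelection:
    """Advancing-front filling of one hole; returns the filled-patch
    selection (EditableMesh ids)."""
    loop = list(hole.loop)
    e_bar = hole.mean_edge_length
    guard = _LocalGuard(em, loop, margin=2.0 * e_bar)
    new_faces: set[int] = set()
    new_vertices: set[int] = set()
    # enough insertions to break deadlocks without letting a large hole
    # degenerate into hundreds of guarded full-lap scans
    stall_budget = 2 * len(loop) + 20

    def add_patch_face(a: int, b: int, c: int) -> int:
        fid = em.add_face(a, b, c)
        new_faces.add(fid)
        guard.add(fid)
        return fid

    cursor = 0
    last_stall: tuple | None = None
    while len(loop) > 3:
        n = len(loop)
        placed = False
        # walk the queue from the current front position so accepted ears
        # alternate around the loop (restarting at the head would grow
        # high-valence fans whose minimum angles are topologically capped)
        for step in range(n):
            i = (cursor + step) % n
            a, b, c = loop[i], loop[(i + 1) % n], loop[(i + 2) % n]
            if a == c or em.has_edge(a, c):
                continue
            if _ear_min_angle(em, a, b, c) < FILL_MIN_ANGLE:
                continue
            if guard.intersects((a, b, c)):
                continue
            add_patch_face(a, b, c)
            del loop[(i + 1) % n]
            cursor = (i + 1) % len(loop)
            placed = True
            break
        if placed:
            last_stall = None
            continue
        if stall_budget > 0 and tuple(loop) != last_stall:
            last_stall = tuple(loop)
            stall_budget -= 1
            centroid = np.mean([em.V[v] for v in loop], axis=0)
            if projector is not None:
                proj = projector.project_one(centroid)
                # deep holes can project far sideways (e.g. onto another
                # sheet); cap the snap to keep the new vertex in the hole
                if np.linalg.norm(proj - centroid) <= 2.0 * max(e_bar, 1e-12):
                    centroid = proj
            m = em.add_vertex(centroid)
            new_vertices.add(m)
            # attach the new vertex where its triangle clears the guard
            spot = 0
            for i in range(n):
                a, b = loop[i], loop[(i + 1) % n]
                if not guard.intersects((a, b, m)):
                    spot = i
                    break
            a, b = loop[spot], loop[(spot + 1) % n]
            add_patch_face(a, b, m)
            loop.insert(spot + 1, m)
        else:
            # force-fill fallback: best remaining ear by min angle, ignoring
            # the 15-degree floor (residuals are caught by the next cut
            # round); non-intersecting ears are strictly preferred
            best, best_ang, best_clean = None, -1.0, False
            for i in range(n):
                a, b, c = loop[i], loop[(i + 1) % n], loop[(i + 2) % n]
                if a == c or em.has_edge(a, c):
                    continue
                ang = _ear_min_angle(em, a, b, c)
                clean = not guard.intersects((a, b, c))
                if (clean, ang) > (best_clean, best_ang):
                    best, best_ang, best_clean = i, ang, clean
            if best is None:
                raise InvalidHoleError("hole cannot be triangulated")
            i = best
            a, b, c = loop[i], loop[(i + 1) % n], loop[(i + 2) % n]
            add_patch_face(a, b, c)
            del loop[(i + 1) % n]

    while True:
        a, b, c = loop
        flap = em.vf.get(a, set()) & em.vf.get(b, set()) & em.vf.get(c, set())
        if flap:
            # the hole is the mirror of a single existing triangle (a flap);
            # capping it would create a degenerate two-face pillow — remove
            # the flap instead, which removes the component
            for fid in flap:
                em.remove_face(fid)
                new_faces.discard(fid)
                guard.remove(fid)
            for vid in (a, b, c):
                em.remove_isolated_vertex(vid)
            break
        if stall_budget > 0 and guard.intersects((a, b, c)):
            # the closing cap would cross nearby geometry: pull it apart by
            # inserting the (projected) centroid and capping with the fan
            stall_budget = 0  # one rescue only; the fan closes immediately
            centroid = np.mean([em.V[v] for v in loop], axis=0)
            if projector is not None:
                centroid = projector.project_one(centroid)
            m = em.add_vertex(centroid)
            new_vertices.add(m)
            for i in range(3):
                add_patch_face(loop[i], loop[(i + 1) % 3], m)
            break
        add_patch_face(a, b, c)
        break

    # 0.7 * mean-edge rule: each edge created by the triangulation that is
    # longer than 0.7 e_bar is split once at its midpoint (children are not
    # revisited — repeated halving would cascade; later local smoothing
    # refines the patch further)
    if e_bar > 0:
        original = set()
        nloop = hole.loop
        for i in range(len(nloop)):
            u, v = nloop[i], nloop[(i + 1) % len(nloop)]
            original.add((u, v) if u < v else (v, u))
        edges = set()
        for fid in list(new_faces):
            if fid not in em.F:
                continue
            fa, fb, fc = em.F[fid]
            for u, v in ((fa, fb), (fb, fc), (fc, fa)):
                e = (u, v) if u < v else (v, u)
                if e not in original:
                    edges.add(e)
        for u, v in sorted(edges):
            if u not in em.V or v not in em.V or not em.has_edge(u, v):
                continue
            if em.edge_length(u, v) <= SPLIT_FACTOR * e_bar:
                continue
            # only edges interior to the patch are split
            if not all(f in new_faces for f in em.faces_of_edge(u, v)):
                continue
            for f in em.faces_of_edge(u, v):
                new_faces.discard(f)
                guard.remove(f)
            mid = 0.5 * (em.V[u] + em.V[v])
            m, children = em.split_edge(u, v, mid)
            new_vertices.add(m)
            for f in children:
                new_faces.add(f)
                guard.add(f)

    verts = {v for fid in new_faces for v in em.F[fid]} | new_vertices
    return RegionSelection(faces=new_faces, vertices=verts, kind="filled-patch")


def fill_hole(mesh: TriangleMesh, hole: HoleBoundary,
              reference: TriangleMesh | None = None
              ) -> tuple[TriangleMesh, RegionSelection]:
    """Fill one hole of an open mesh; returns the closed-over mesh and the
    filled-patch selection (indexed against the returned mesh)."""
    em = EditableMesh.from_mesh(mesh)
    projector = (
        MeshProjector(reference.vertices, reference.faces)
        if reference is not None else None
    )
    patch = _fill_em(em, hole, projector)
    out, vid_map, fid_map = em.to_mesh()
    return out, RegionSelection(
        faces={fid_map[f] for f in patch.faces},
        vertices={vid_map[v] for v in patch.vertices},
        kind="filled-patch",
    )


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def cut_and_fill(mesh: TriangleMesh, theta_min: float,
                 reference: TriangleMesh | None = None,
                 rings: int = 1) -> tuple[TriangleMesh, list[RegionSelection]]:
    """Label small triangles and narrow regions, cut them (with ``rings``
    one-ring dilations of the small triangles), and refill every hole.

    Returns the closed mesh and the filled patches for local smoothing.
    A clean mesh comes back unchanged with no patches.
    """
    regions = (invalid_regions(mesh, theta_min, rings=rings)
               + detect_narrow_regions(mesh, theta_min))
    if not regions:
        return mesh, []
    projector = None
    if reference is not None:
        projector = MeshProjector(reference.vertices, reference.faces)

    em = EditableMesh.from_mesh(mesh)
    holes = _cut_em(em, {f for r in regions for f in r.faces})
    patches = [_fill_em(em, h, projector) for h in holes]
    out, vid_map, fid_map = em.to_mesh()
    remapped = [
        RegionSelection(
            faces={fid_map[f] for f in p.faces if f in fid_map},
            vertices={vid_map[v] for v in p.vertices if v in vid_map},
            kind="filled-patch",
        )
        for p in patches
    ]
    return out, [p for p in remapped if p.faces]
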