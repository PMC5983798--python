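"""Local smoothing of freshly filled patches.

Three operators run in sequence over each filled patch:

1. collapse edges whose opposite angle (the angle facing the edge in an
   incident triangle) is below 30 degrees — slivers die at their base;
2. split edges with an opposite angle above 90 degrees at the projection
   of the obtuse vertex onto the edge — the obtuse corner becomes two
   right-ish corners (this never lowers the triangle's minimum angle);
3. stochastic vertex relocation: for each patch vertex, candidates
   v_f = c_i + k * delta_d * l_bar around the Laplacian center c_i are
   drawn for a descending step schedule delta_d (1, 1/2, 1/4, 1/6,
   1/8, ... down to a terminal epsilon) and m random tangent-plane unit
   directions k per step, scaled by the local mean edge length l_bar; a
   candidate is kept only if it strictly improves the minimum angle over
   the vertex's incident faces (projected to the reference surface
   first, so the improvement holds for the written position).

Every operator is guarded so the minimum angle over each patch never
decreases, and vertices outside the patches and their one-rings are
never touched.  All randomness flows from the schedule's seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _geometry as geom
from ._edit import EditableMesh
from ._geometry import MeshProjector
from .cut_fill import RegionSelection
from .mesh_core import TriangleMesh

__all__ = [
    "SmoothingSchedule",
    "collapse_short_edges",
    "split_long_edges",
    "stochastic_vertex_optimize",
    "smooth_filled_regions",
]

OPPOSITE_COLLAPSE_DEG = 30.0
OPPOSITE_SPLIT_DEG = 90.0


def _default_deltas(epsilon: float) -> tuple[float, ...]:
    """1, 1/2, 1/4, 1/6, 1/8, ... (1 then 1/(2j)) down to epsilon."""
    out = [1.0]
    j = 1
    while True:
        d = 1.0 / (2 * j)
        if d < epsilon:
            break
        out.append(d)
        j += 1
    return tuple(out)


@dataclass
class SmoothingSchedule:
    """Step sizes (fractions of the local mean edge length), terminal
    epsilon, directions per step, and the RNG seed."""

    epsilon: float = 0.01
    deltas: tuple[float, ...] | None = None
    directions_per_step: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.directions_per_step < 1:
            raise ValueError("directions_per_step must be >= 1")
        if self.deltas is None:
            self.deltas = _default_deltas(self.epsilon)
        self.deltas = tuple(self.deltas)
        if any(b >= a for a, b in zip(self.deltas, self.deltas[1:])):
            raise ValueError("delta sequence must be strictly decreasing")
        if self.deltas and self.deltas[-1] < self.epsilon:
            raise ValueError("delta sequence must end at or above epsilon")


# ---------------------------------------------------------------------------
# edge operators
# ---------------------------------------------------------------------------

def _opposite_angles(em: EditableMesh, u: int, v: int) -> list[tuple[float, int, int]]:
    """(angle at opposite vertex, fid, opposite vid) per incident face."""
    out = []
    for fid in em.faces_of_edge(u, v):
        w = em.opposite_vertex(fid, u, v)
        try:
            angs = em.face_angles(fid)
        except ValueError:
            continue
        slot = em.F[fid].index(w)
        out.append((angs[slot], fid, w))
    return out


def _region_edges(em: EditableMesh, faces: set[int]):
    edges = set()
    for fid in faces:
        if fid not in em.F:
            continue
        a, b, c = em.F[fid]
        for x, y in ((a, b), (b, c), (c, a)):
            edges.add((x, y) if x < y else (y, x))
    return edges


def _local_min_angle(em: EditableMesh, fids) -> float:
    best = math.inf
    for fid in fids:
        if fid in em.F:
            best = min(best, em.face_min_angle(fid))
    return best


class _ProximityGuard:
    """Intersection guard for local operators.

    Collects the faces near a patch once (AABB overlap with the patch box,
    expanded by a margin), then screens candidate triangles against them:
    a vectorized broad phase over build-time face boxes (inflated by the
    margin to absorb drift while vertices move) followed by the exact
    triangle-triangle test on live coordinates.  Shared-vertex pairs are
    never obstacles.
    """

    def __init__(self, em: EditableMesh, patch_vertices, margin: float):
        self.em = em
        self.margin = margin
        pts = np.array([em.V[v] for v in patch_vertices if v in em.V])
        if len(pts) == 0:
            self.fids: list[int] = []
            self.lo = np.zeros((0, 3))
            self.hi = np.zeros((0, 3))
            return
        lo = pts.min(axis=0) - 3.0 * margin
        hi = pts.max(axis=0) + 3.0 * margin
        fids, boxes_lo, boxes_hi = [], [], []
        for fid, f in em.F.items():
            T = np.array([em.V[v] for v in f])
            tlo = T.min(axis=0)
            thi = T.max(axis=0)
            if (thi < lo).any() or (tlo > hi).any():
                continue
            fids.append(fid)
            # boxes are stale while vertices move: inflate beyond the
            # largest plausible relocation (ring radius + one step) so the
            # broad phase cannot miss a moved obstacle; the narrow phase
            # always reads live coordinates
            boxes_lo.append(tlo - 3.0 * margin)
            boxes_hi.append(thi + 3.0 * margin)
        self.fids = fids
        self.lo = np.array(boxes_lo) if fids else np.zeros((0, 3))
        self.hi = np.array(boxes_hi) if fids else np.zeros((0, 3))

    def intersects(self, tris: list[tuple[np.ndarray, tuple[int, ...]]],
                   exclude: set[int]) -> bool:
        """tris: (coords (3,3), vertex-id triple) candidates to place."""
        em = self.em
        if not self.fids:
            return False
        for T, vids in tris:
            T = np.asarray(T)
            tlo = T.min(axis=0)
            thi = T.max(axis=0)
            hit = ~((self.hi < tlo).any(axis=1) | (self.lo > thi).any(axis=1))
            vs = set(vids)
            for j in np.nonzero(hit)[0]:
                fid = self.fids[j]
                if fid in exclude or fid not in em.F:
                    continue
                # skip shared-edge neighbors only; one shared vertex still
                # needs the exact test (folds pass through shared vertices)
                if len(vs & set(em.F[fid])) >= 2:
                    continue
                O = np.array(em.face_points(fid))
                if (O.max(axis=0) < tlo).any() or (O.min(axis=0) > thi).any():
                    continue
                if geom.tri_tri_intersect(T, O):
                    return True
        return False


def _collapse_short_em(em: EditableMesh, region: RegionSelection,
                       guard: _ProximityGuard | None = None) -> int:
    """One sweep collapsing region edges whose opposite angle is < 30
    degrees, smallest angle first, guarded against manifold breakage,
    normal flips, and any decrease of the local minimum angle."""
    cands = []
    for u, v in _region_edges(em, region.faces):
        opp = _opposite_angles(em, u, v)
        if not opp:
            continue
        worst = min(a for a, _, _ in opp)
        if worst < OPPOSITE_COLLAPSE_DEG:
            cands.append((worst, u, v))
    cands.sort()
    collapsed = 0
    for _, u, v in cands:
        if u not in em.V or v not in em.V or not em.has_edge(u, v):
            continue
        opp = _opposite_angles(em, u, v)
        if not opp or min(a for a, _, _ in opp) >= OPPOSITE_COLLAPSE_DEG:
            continue
        if not em.can_collapse(u, v):
            continue
        affected = (em.vf[u] | em.vf[v])
        before = _local_min_angle(em, affected)
        shared = set(em.faces_of_edge(u, v))
        mid = 0.5 * (em.V[u] + em.V[v])
        if em.would_flip_normal(u, mid, exclude=shared) or \
           em.would_flip_normal(v, mid, exclude=shared):
            continue
        # simulate: survivors' min angle with both endpoints at mid must
        # not drop below the pre-collapse local minimum
        after = math.inf
        sim_tris = []
        for fid in affected - shared:
            pts = [mid if x in (u, v) else em.V[x] for x in em.F[fid]]
            after = min(after, geom.min_angle_deg(
                tuple(pts[0]), tuple(pts[1]), tuple(pts[2])))
            vids = tuple(u if x == v else x for x in em.F[fid])
            sim_tris.append((np.array(pts), vids))
        if after < before - 1e-9:
            continue
        if guard is not None and guard.intersects(sim_tris, exclude=affected):
            continue
        if em.collapse_edge(u, v, mid):
            for fid in shared:
                region.faces.discard(fid)
            region.vertices.discard(v)
            collapsed += 1
    return collapsed


def _split_long_em(em: EditableMesh, region: RegionSelection) -> int:
    """One sweep splitting region edges whose opposite angle exceeds 90
    degrees at the projection of the obtuse vertex onto the edge.

    The split is skipped when the foot of the obtuse vertex falls outside
    the open segment (extremely skewed triangles) — splitting there cannot
    cure the obtuse corner and such faces are left to the collapse pass or
    the next cut round.  Children are not revisited within the sweep, so
    the face count stays bounded.
    """
    split = 0
    for u, v in sorted(_region_edges(em, region.faces)):
        if u not in em.V or v not in em.V or not em.has_edge(u, v):
            continue
        opp = _opposite_angles(em, u, v)
        if not opp:
            continue
        worst = max(opp)
        if worst[0] <= OPPOSITE_SPLIT_DEG:
            continue
        w = worst[2]
        pu, pv, pw = em.V[u], em.V[v], em.V[w]
        e = pv - pu
        ee = float(np.dot(e, e))
        if ee == 0.0:
            continue
        t = float(np.dot(pw - pu, e)) / ee
        if not (0.05 <= t <= 0.95):
            continue
        fids = em.faces_of_edge(u, v)
        if len(fids) == 2 and set(em.F[fids[0]]) == set(em.F[fids[1]]):
            continue  # degenerate pillow pair: splitting would break manifoldness
        in_region = [f in region.faces for f in em.faces_of_edge(u, v)]
        m, children = em.split_edge(u, v, pu + t * e)
        region.vertices.add(m)
        # children come in pairs per incident face, in face order
        fids = iter(children)
        for was_region in in_region:
            c1, c2 = next(fids), next(fids)
            if was_region:
                region.faces.update((c1, c2))
        # parent fids are gone
        region.faces &= set(em.F)
        split += 1
    return split


def _flip_improve_em(em: EditableMesh, region: RegionSelection,
                     guard: _ProximityGuard | None = None) -> int:
    """Lawson-style flips of patch-interior edges that strictly raise the
    local minimum angle.

    Advancing-front triangulations of large holes leave high-valence hub
    vertices; around a planar valence-k vertex the minimum incident angle
    is capped near 360/k degrees, so no amount of vertex relocation can
    reach the 30-degree bound without these topology moves.  Edges with at
    least one region face are eligible (boundary valence defects straddle
    the patch rim); flipped faces join the region.  Flips preserve
    orientation and (when a guard is given) may not introduce
    intersections; no vertex moves.
    """
    flipped = 0
    for _ in range(5):
        progress = False
        for u, v in sorted(_region_edges(em, region.faces)):
            if u not in em.V or v not in em.V:
                continue
            fids = em.faces_of_edge(u, v)
            if len(fids) != 2 or not any(f in region.faces for f in fids):
                continue
            a = em.opposite_vertex(fids[0], u, v)
            b = em.opposite_vertex(fids[1], u, v)
            if a == b or em.has_edge(a, b):
                continue
            old_min = min(em.face_min_angle(fids[0]), em.face_min_angle(fids[1]))
            pa, pb, pu, pv = em.V[a], em.V[b], em.V[u], em.V[v]
            new1 = geom.min_angle_deg(tuple(pu), tuple(pb), tuple(pa))
            new2 = geom.min_angle_deg(tuple(pv), tuple(pa), tuple(pb))
            if min(new1, new2) <= old_min + 1e-9:
                continue
            n_old = em.face_normal(fids[0]) + em.face_normal(fids[1])
            n1 = np.cross(pb - pu, pa - pu)
            n2 = np.cross(pa - pv, pb - pv)
            if float(np.dot(n_old, n1)) <= 0 or float(np.dot(n_old, n2)) <= 0:
                continue
            if guard is not None and guard.intersects(
                [(np.array([pu, pb, pa]), (u, b, a)),
                 (np.array([pv, pa, pb]), (v, a, b))],
                exclude=set(fids),
            ):
                continue
            if em.flip_edge(u, v):
                region.faces.discard(fids[0])
                region.faces.discard(fids[1])
                # the two replacement faces are the most recent ids
                new_ids = em.faces_of_edge(a, b)
                region.faces.update(new_ids)
                flipped += 1
                progress = True
        if not progress:
            break
    return flipped


# ---------------------------------------------------------------------------
# stochastic relocation
# ---------------------------------------------------------------------------

def _tangent_frame(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = normal
    if np.linalg.norm(n) == 0:
        n = np.array([0.0, 0.0, 1.0])
    a = np.array([1.0, 0.0, 0.0])
    if abs(float(np.dot(a, n))) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    t1 = np.cross(n, a)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(n, t1)
    t2 /= np.linalg.norm(t2)
    return t1, t2


def _candidate_min_angles(cand: np.ndarray, fixed: np.ndarray) -> np.ndarray:
    """Min interior angle (deg) of triangles (x, p, q) for each candidate x.

    cand: (m, 3); fixed: (k, 2, 3) the two other corners per incident face.
    Returns (m,) minima over faces and corners.
    """
    p = fixed[:, 0]  # (k, 3)
    q = fixed[:, 1]
    a = np.linalg.norm(p - q, axis=1)  # (k,) opposite the moving vertex
    b = np.linalg.norm(cand[:, None, :] - q[None], axis=2)  # (m, k)
    c = np.linalg.norm(cand[:, None, :] - p[None], axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos_x = (b * b + c * c - a * a) / (2 * b * c)
        cos_p = (a * a + c * c - b * b) / (2 * a * c)
        cos_q = (a * a + b * b - c * c) / (2 * a * b)
    ang = np.arccos(np.clip(np.nan_to_num(
        np.stack([cos_x, cos_p, cos_q], axis=0), nan=1.0), -1.0, 1.0))
    return np.degrees(ang).min(axis=(0, 2))


def _optimize_vertex(em: EditableMesh, vid: int, region_faces: set[int],
                     schedule: SmoothingSchedule, rng: np.random.Generator,
                     projector: MeshProjector | None,
                     guard: _ProximityGuard | None = None) -> bool:
    fids = sorted(em.vf.get(vid, ()))
    if not fids:
        return False
    nbrs = sorted(em.vertex_neighbors(vid))
    if len(nbrs) < 3:
        return False
    c_i = np.mean([em.V[n] for n in nbrs], axis=0)
    l_bar = em.local_mean_edge_length(vid)
    if l_bar == 0.0:
        return False
    normal = em.vertex_normal(vid)
    t1, t2 = _tangent_frame(normal)

    # fixed corner pairs, face order preserved relative to the moving vertex
    fixed = []
    patch_mask = []
    old_normals = []
    for fid in fids:
        tri = list(em.F[fid])
        slot = tri.index(vid)
        p = em.V[tri[(slot + 1) % 3]]
        q = em.V[tri[(slot + 2) % 3]]
        fixed.append([p, q])
        patch_mask.append(fid in region_faces)
        old_normals.append(em.face_normal(fid))
    fixed = np.asarray(fixed)
    patch_mask = np.asarray(patch_mask)
    old_normals = np.asarray(old_normals)

    def mins_at(pos: np.ndarray) -> tuple[float, float]:
        m = _candidate_min_angles(pos[None], fixed)
        mp = (
            _candidate_min_angles(pos[None], fixed[patch_mask])
            if patch_mask.any() else np.array([math.inf])
        )
        return float(m[0]), float(mp[0])

    cur_all, cur_patch = mins_at(em.V[vid])
    moved = False
    m = schedule.directions_per_step
    for delta in schedule.deltas:
        theta = rng.random(m) * 2.0 * math.pi
        dirs = np.cos(theta)[:, None] * t1 + np.sin(theta)[:, None] * t2
        cands = c_i[None] + dirs * (delta * l_bar)
        pre = _candidate_min_angles(cands, fixed)
        order = np.argsort(-pre)  # most promising first
        for j in order:
            if pre[j] <= cur_all:
                break  # no unprojected candidate can improve
            pos = cands[j]
            if projector is not None:
                pos = projector.project_one(pos)
                if np.linalg.norm(pos - cands[j]) > 2.0 * l_bar:
                    continue  # projection snapped far away; distrust it
            new_all, new_patch = mins_at(pos)
            if not (new_all > cur_all and new_patch >= cur_patch - 1e-12):
                continue
            # orientation guard
            new_n = np.cross(fixed[:, 0] - pos, fixed[:, 1] - pos)
            if (np.einsum("ij,ij->i", new_n, old_normals) <= 0.0).any():
                continue
            if guard is not None:
                sim = [
                    (np.array([pos, fixed[t, 0], fixed[t, 1]]), em.F[fid])
                    for t, fid in enumerate(fids)
                ]
                if guard.intersects(sim, exclude=set(fids)):
                    continue
            em.V[vid] = np.asarray(pos, dtype=float).copy()
            cur_all, cur_patch = new_all, new_patch
            moved = True
            break
    return moved


# ---------------------------------------------------------------------------
# public wrappers
# ---------------------------------------------------------------------------

def _remap_region(region: RegionSelection, vid_map, fid_map) -> RegionSelection:
    return RegionSelection(
        faces={fid_map[f] for f in region.faces if f in fid_map},
        vertices={vid_map[v] for v in region.vertices if v in vid_map},
        kind=region.kind,
    )


def collapse_short_edges(mesh: TriangleMesh, region: RegionSelection) -> TriangleMesh:
    """Collapse region edges with an opposite angle < 30 degrees."""
    em = EditableMesh.from_mesh(mesh)
    reg = RegionSelection(set(region.faces), set(region.vertices), region.kind)
    _collapse_short_em(em, reg)
    out, _, _ = em.to_mesh()
    return out


def split_long_edges(mesh: TriangleMesh, region: RegionSelection) -> TriangleMesh:
    """Split region edges with an opposite angle > 90 degrees."""
    em = EditableMesh.from_mesh(mesh)
    reg = RegionSelection(set(region.faces), set(region.vertices), region.kind)
    _split_long_em(em, reg)
    out, _, _ = em.to_mesh()
    return out


def stochastic_vertex_optimize(mesh: TriangleMesh, region: RegionSelection,
                               schedule: SmoothingSchedule,
                               reference: TriangleMesh | None = None) -> TriangleMesh:
    """Relocate region vertices by the seeded stochastic schedule; the
    minimum angle around each vertex never decreases."""
    em = EditableMesh.from_mesh(mesh)
    rng = np.random.default_rng(schedule.seed)
    projector = (
        MeshProjector(reference.vertices, reference.faces)
        if reference is not None else None
    )
    for vid in sorted(region.vertices):
        if vid in em.V:
            _optimize_vertex(em, vid, region.faces, schedule, rng, projector)
    out, _, _ = em.to_mesh()
    return out


def smooth_filled_regions(mesh: TriangleMesh, patches: list[RegionSelection],
                          schedule: SmoothingSchedule | None = None,
                          reference: TriangleMesh | None = None) -> TriangleMesh:
    """Collapse, split, then stochastically optimize every filled patch.

    Region membership is maintained across the topology edits; the
    per-patch minimum angle is non-decreasing across the call, and faces
    outside the patches' one-rings are untouched.
    """
    if not patches:
        return mesh
    if schedule is None:
        schedule = SmoothingSchedule()
    em = EditableMesh.from_mesh(mesh)
    rng = np.random.default_rng(schedule.seed)
    projector = (
        MeshProjector(reference.vertices, reference.faces)
        if reference is not None else None
    )
    for patch in patches:
        reg = RegionSelection(set(patch.faces), set(patch.vertices), patch.kind)
        reg.faces &= set(em.F)
        reg.vertices &= set(em.V)
        if not reg.faces:
            continue
        verts0 = set(reg.vertices)
        for fid in reg.faces:
            verts0.update(em.F[fid])
        margin = 1.5 * float(np.mean([
            em.edge_length(u, v) for u, v in _region_edges(em, reg.faces)
        ]))
        guard = _ProximityGuard(em, verts0, margin)
        _collapse_short_em(em, reg, guard)
        _split_long_em(em, reg)
        _flip_improve_em(em, reg, guard)
        verts = set(reg.vertices)
        for fid in reg.faces:
            verts.update(em.F[fid])
        guard = _ProximityGuard(em, verts, margin)
        for vid in sorted(verts):
            if vid in em.V:
                _optimize_vertex(em, vid, reg.faces, schedule, rng, projector, guard)
        _flip_improve_em(em, reg, guard)
    out, _, _ = em.to_mesh()
    return out
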