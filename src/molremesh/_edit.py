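"""Editable halfedge-free mesh used by the local remeshing operators.

Vertices and faces live in id-keyed dicts so that split / collapse / flip
can run incrementally without re-indexing; :meth:`EditableMesh.to_mesh`
compacts ids back into array form deterministically (ascending id order).
Edge incidence is recovered from per-vertex face sets (``vf[u] & vf[v]``),
which keeps every local query O(vertex degree).

All topology guards needed by the pipeline live here:

* collapse uses the link condition plus duplicate-face rejection, so an
  edge-manifold mesh stays edge-manifold;
* flips require the target edge to be absent;
* splits preserve orientation on both incident faces.
"""
from __future__ import annotations

import math

import numpy as np

from . import _geometry as geom


class EditableMesh:
    def __init__(self):
        self.V: dict[int, np.ndarray] = {}
        self.F: dict[int, tuple[int, int, int]] = {}
        self.vf: dict[int, set[int]] = {}
        self._next_v = 0
        self._next_f = 0

    # -- construction -------------------------------------------------------

    @classmethod
    def from_mesh(cls, mesh) -> "EditableMesh":
        """Build from a TriangleMesh; vertex/face ids equal the row indices."""
        em = cls()
        for i, p in enumerate(mesh.vertices):
            em.V[i] = np.array(p, dtype=float)
            em.vf[i] = set()
        for i, (a, b, c) in enumerate(mesh.faces):
            f = (int(a), int(b), int(c))
            em.F[i] = f
            for v in f:
                em.vf[v].add(i)
        em._next_v = len(mesh.vertices)
        em._next_f = len(mesh.faces)
        return em

    def to_mesh(self, drop_isolated: bool = True):
        """Compact into a TriangleMesh; returns (mesh, vid_map, fid_map)."""
        from .mesh_core import TriangleMesh

        used = set()
        for f in self.F.values():
            used.update(f)
        vids = sorted(used) if drop_isolated else sorted(self.V)
        vid_map = {v: i for i, v in enumerate(vids)}
        fids = sorted(self.F)
        fid_map = {f: i for i, f in enumerate(fids)}
        verts = np.array([self.V[v] for v in vids]) if vids else np.zeros((0, 3))
        faces = np.array(
            [[vid_map[a], vid_map[b], vid_map[c]] for a, b, c in (self.F[f] for f in fids)],
            dtype=np.int64,
        ) if fids else np.zeros((0, 3), dtype=np.int64)
        return TriangleMesh(verts, faces, validate=False), vid_map, fid_map

    # -- basic queries -------------------------------------------------------

    def add_vertex(self, pos) -> int:
        vid = self._next_v
        self._next_v += 1
        self.V[vid] = np.asarray(pos, dtype=float).copy()
        self.vf[vid] = set()
        return vid

    def add_face(self, a: int, b: int, c: int) -> int:
        fid = self._next_f
        self._next_f += 1
        self.F[fid] = (a, b, c)
        for v in (a, b, c):
            self.vf[v].add(fid)
        return fid

    def remove_face(self, fid: int) -> None:
        for v in self.F.pop(fid):
            self.vf[v].discard(fid)

    def remove_isolated_vertex(self, vid: int) -> None:
        if vid in self.V and not self.vf.get(vid):
            del self.V[vid]
            self.vf.pop(vid, None)

    def faces_of_edge(self, u: int, v: int) -> list[int]:
        if u not in self.vf or v not in self.vf:
            return []
        return [f for f in self.vf[u] & self.vf[v]]

    def has_edge(self, u: int, v: int) -> bool:
        return bool(self.vf.get(u, set()) & self.vf.get(v, set()))

    def vertex_neighbors(self, v: int) -> set[int]:
        out: set[int] = set()
        for fid in self.vf.get(v, ()):
            out.update(self.F[fid])
        out.discard(v)
        return out

    def face_points(self, fid: int):
        a, b, c = self.F[fid]
        return self.V[a], self.V[b], self.V[c]

    def face_normal(self, fid: int):
        p0, p1, p2 = self.face_points(fid)
        return np.cross(p1 - p0, p2 - p0)

    def face_min_angle(self, fid: int) -> float:
        p0, p1, p2 = self.face_points(fid)
        return geom.min_angle_deg(tuple(p0), tuple(p1), tuple(p2))

    def face_angles(self, fid: int):
        p0, p1, p2 = self.face_points(fid)
        return geom.angles_deg(tuple(p0), tuple(p1), tuple(p2))

    def edge_length(self, u: int, v: int) -> float:
        return float(np.linalg.norm(self.V[u] - self.V[v]))

    def edges(self):
        """Iterate unique undirected edges as sorted tuples."""
        seen: set[tuple[int, int]] = set()
        for a, b, c in self.F.values():
            for u, v in ((a, b), (b, c), (c, a)):
                e = (u, v) if u < v else (v, u)
                if e not in seen:
                    seen.add(e)
                    yield e

    def boundary_edges(self):
        """Unique edges with exactly one incident face."""
        for u, v in self.edges():
            if len(self.faces_of_edge(u, v)) == 1:
                yield (u, v)

    def directed_edge_in_face(self, fid: int, u: int, v: int) -> bool:
        """True when u->v appears in the face's cyclic (CCW) order."""
        a, b, c = self.F[fid]
        return (a, b) == (u, v) or (b, c) == (u, v) or (c, a) == (u, v)

    def opposite_vertex(self, fid: int, u: int, v: int) -> int:
        for w in self.F[fid]:
            if w != u and w != v:
                return w
        raise ValueError("edge not in face")

    # -- local operators ------------------------------------------------------

    def split_edge(self, u: int, v: int, point) -> tuple[int, list[int]]:
        """Split edge (u, v) at ``point``; returns (new vid, new face ids).

        Each incident face (u, v, w) is replaced by two orientation-
        preserving children.
        """
        fids = self.faces_of_edge(u, v)
        m = self.add_vertex(point)
        new_faces: list[int] = []
        for fid in fids:
            w = self.opposite_vertex(fid, u, v)
            forward = self.directed_edge_in_face(fid, u, v)
            self.remove_face(fid)
            if forward:
                new_faces.append(self.add_face(u, m, w))
                new_faces.append(self.add_face(m, v, w))
            else:
                new_faces.append(self.add_face(v, m, w))
                new_faces.append(self.add_face(m, u, w))
        return m, new_faces

    def can_collapse(self, u: int, v: int) -> bool:
        """Link condition + duplicate-face rejection for edge (u, v)."""
        shared = self.faces_of_edge(u, v)
        if not shared:
            return False
        opposite = {self.opposite_vertex(f, u, v) for f in shared}
        common = self.vertex_neighbors(u) & self.vertex_neighbors(v)
        if common != opposite:
            return False
        # reject pillow/duplicate outcomes: vertex sets of surviving faces
        survivors = []
        for fid in (self.vf[u] | self.vf[v]) - set(shared):
            fs = frozenset(u if x == v else x for x in self.F[fid])
            if len(fs) < 3:
                return False
            survivors.append(fs)
        return len(survivors) == len(set(survivors))

    def collapse_edge(self, u: int, v: int, point) -> bool:
        """Collapse (u, v) onto ``point``, merging v into u.

        Caller must have verified :meth:`can_collapse` plus any geometric
        guards; returns False if the topological guard fails.
        """
        if not self.can_collapse(u, v):
            return False
        for fid in self.faces_of_edge(u, v):
            self.remove_face(fid)
        for fid in list(self.vf.get(v, ())):
            a, b, c = self.F[fid]
            f = tuple(u if x == v else x for x in (a, b, c))
            for x in (a, b, c):
                self.vf[x].discard(fid)
            self.F[fid] = f
            for x in f:
                self.vf[x].add(fid)
        self.V[u] = np.asarray(point, dtype=float).copy()
        self.remove_isolated_vertex(v)
        return True

    def flip_edge(self, u: int, v: int) -> bool:
        """Flip interior edge (u, v); returns False if the flip is illegal."""
        fids = self.faces_of_edge(u, v)
        if len(fids) != 2:
            return False
        if self.directed_edge_in_face(fids[0], u, v):
            f1, f2 = fids
        elif self.directed_edge_in_face(fids[1], u, v):
            f2, f1 = fids
        else:
            return False
        a = self.opposite_vertex(f1, u, v)  # f1 contains u->v
        b = self.opposite_vertex(f2, u, v)  # f2 contains v->u
        if a == b or self.has_edge(a, b):
            return False
        self.remove_face(f1)
        self.remove_face(f2)
        self.add_face(u, b, a)
        self.add_face(v, a, b)
        return True

    # -- geometric helpers used by guards --------------------------------------

    def would_flip_normal(self, vid: int, new_pos, exclude: set[int] | None = None,
                          cos_limit: float = 0.0) -> bool:
        """True if moving ``vid`` to ``new_pos`` reverses a valid incident
        normal or makes a non-degenerate face degenerate.

        Faces that are already degenerate (zero-area) never veto a move —
        any relocation of a sliver corner is an improvement.
        """
        new_pos = np.asarray(new_pos, dtype=float)
        for fid in self.vf.get(vid, ()):
            if exclude and fid in exclude:
                continue
            a, b, c = self.F[fid]
            pts_old = [self.V[x] for x in (a, b, c)]
            pts_new = [new_pos if x == vid else self.V[x] for x in (a, b, c)]
            n_old = np.cross(pts_old[1] - pts_old[0], pts_old[2] - pts_old[0])
            h2_old = max(
                float(np.dot(pts_old[i] - pts_old[j], pts_old[i] - pts_old[j]))
                for i, j in ((0, 1), (1, 2), (2, 0))
            )
            # area = |n|/2; degenerate when area < 1e-12 h^2
            if float(np.dot(n_old, n_old)) <= (2e-12 * h2_old) ** 2:
                continue
            n_new = np.cross(pts_new[1] - pts_new[0], pts_new[2] - pts_new[0])
            h2_new = max(
                float(np.dot(pts_new[i] - pts_new[j], pts_new[i] - pts_new[j]))
                for i, j in ((0, 1), (1, 2), (2, 0))
            )
            if float(np.dot(n_new, n_new)) <= (2e-12 * h2_new) ** 2:
                return True
            denom = float(np.linalg.norm(n_old) * np.linalg.norm(n_new))
            if float(np.dot(n_old, n_new)) <= cos_limit * denom:
                return True
        return False

    def vertex_normal(self, vid: int) -> np.ndarray:
        """Area-weighted vertex normal (zero vector for isolated vertices)."""
        n = np.zeros(3)
        for fid in self.vf.get(vid, ()):
            n += self.face_normal(fid)
        norm = np.linalg.norm(n)
        return n / norm if norm > 0 else n

    def local_mean_edge_length(self, vid: int) -> float:
        nbrs = self.vertex_neighbors(vid)
        if not nbrs:
            return 0.0
        return float(np.mean([self.edge_length(vid, n) for n in nbrs]))

    def min_angle_around(self, vid: int, pos=None, faces=None) -> float:
        """Minimum interior angle over faces incident to ``vid``.

        ``pos`` substitutes the vertex position; ``faces`` restricts the
        face set.
        """
        fids = self.vf.get(vid, set())
        if faces is not None:
            fids = fids & faces
        best = math.inf
        for fid in fids:
            pts = [
                (pos if (pos is not None and x == vid) else self.V[x])
                for x in self.F[fid]
            ]
            ang = geom.min_angle_deg(tuple(pts[0]), tuple(pts[1]), tuple(pts[2]))
            if ang < best:
                best = ang
        return best
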