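"""Global aspect-ratio improvement by guarded vertex relocation.

Every vertex is offered up to two candidate positions — the centroid of
its mixed Voronoi cell (CVT style), then the Laplacian center of its
one-ring — and moves to the first candidate that strictly lowers its
vertex aspect ratio ARv (the mean AR of its incident triangles, with the
undefined sentinel counting as +inf so any move away from degeneracy is
an improvement).

Beyond the ARv test, an accepted move must not flip any incident face
normal, must not turn a finite triangle AR undefined, and must not
increase the valence-weighted sum of finite incident-triangle ARs.  The
last guard makes the pass-level invariant exact: the mean finite ARv
over the mesh never increases across a pass.  Candidates are projected
to the reference surface *before* evaluation, so the guarantee holds for
the positions actually written.

Topology is never modified; only vertex positions move.
"""
from __future__ import annotations

import math

import numpy as np

from . import _geometry as geom
from ._geometry import UNDEFINED, MeshProjector
from .errors import DegenerateRingError
from .mesh_core import TriangleMesh

__all__ = ["laplacian_center", "cvt_centroid", "improve_aspect_ratios"]


def _ring_vertices(mesh: TriangleMesh, vertex: int) -> set[int]:
    ring: set[int] = set()
    for fi in mesh.vertex_faces[vertex]:
        ring.update(int(x) for x in mesh.faces[fi])
    ring.discard(vertex)
    return ring


def laplacian_center(mesh: TriangleMesh, vertex: int) -> np.ndarray:
    """Arithmetic mean of the one-ring neighbor positions."""
    ring = _ring_vertices(mesh, vertex)
    if len(ring) < 3:
        raise DegenerateRingError(f"vertex {vertex} has a one-ring of size {len(ring)}")
    return mesh.vertices[sorted(ring)].mean(axis=0)


def _circumcenter(a, b, c):
    ab = b - a
    ac = c - a
    n = np.cross(ab, ac)
    nn = float(np.dot(n, n))
    if nn == 0.0:
        return None
    ab2 = float(np.dot(ab, ab))
    ac2 = float(np.dot(ac, ac))
    return a + (ac2 * np.cross(n, ab) + ab2 * np.cross(ac, n)) / (2.0 * nn)


def _quad_centroid_area(p0, p1, p2, p3):
    """Centroid and area of the (planar-ish) quad p0 p1 p2 p3 split into
    two triangles at p0."""
    a1 = geom.triangle_area_3d(tuple(p0), tuple(p1), tuple(p2))
    a2 = geom.triangle_area_3d(tuple(p0), tuple(p2), tuple(p3))
    c1 = (p0 + p1 + p2) / 3.0
    c2 = (p0 + p2 + p3) / 3.0
    area = a1 + a2
    if area == 0.0:
        return (p0 + p1 + p2 + p3) / 4.0, 0.0
    return (a1 * c1 + a2 * c2) / area, area


def cvt_centroid(mesh: TriangleMesh, vertex: int) -> np.ndarray:
    """Area-weighted centroid of the vertex's mixed Voronoi cell, projected
    to the vertex tangent plane.

    For each incident triangle (v, p, q) the subcell is the quad
    (v, mid(vp), circumcenter, mid(vq)) when the triangle is non-obtuse,
    and the barycentric quad (v, mid(vp), barycenter, mid(vq)) otherwise.
    A degenerate one-ring falls back to the Laplacian center.
    """
    v = mesh.vertices[vertex]
    fids = mesh.vertex_faces[vertex]
    if not fids:
        raise DegenerateRingError(f"vertex {vertex} has no incident faces")

    acc = np.zeros(3)
    total = 0.0
    normal = np.zeros(3)
    for fi in fids:
        tri = [int(x) for x in mesh.faces[fi]]
        others = [x for x in tri if x != vertex]
        p, q = mesh.vertices[others[0]], mesh.vertices[others[1]]
        fn = np.cross(p - v, q - v)
        normal += fn if np.dot(fn, fn) > 0 else 0.0
        try:
            angs = geom.angles_deg(tuple(v), tuple(p), tuple(q))
        except ValueError:
            continue
        mid_vp = 0.5 * (v + p)
        mid_vq = 0.5 * (v + q)
        if max(angs) <= 90.0 + 1e-12:
            cc = _circumcenter(v, p, q)
            inner = cc if cc is not None else (v + p + q) / 3.0
        else:
            inner = (v + p + q) / 3.0
        c, a = _quad_centroid_area(v, mid_vp, inner, mid_vq)
        acc += a * c
        total += a

    if total <= 0.0:
        return laplacian_center(mesh, vertex)
    centroid = acc / total
    nn = float(np.dot(normal, normal))
    if nn > 0:
        n = normal / math.sqrt(nn)
        d = centroid - v
        centroid = v + (d - float(np.dot(d, n)) * n)
    return centroid


# ---------------------------------------------------------------------------
# Algorithm-2 sweep
# ---------------------------------------------------------------------------

def _face_ar(V, tri) -> float:
    return geom.aspect_ratio_scalar(tuple(V[tri[0]]), tuple(V[tri[1]]), tuple(V[tri[2]]))


def _vertex_ar_from(face_ars: dict[int, float], fids) -> float:
    total = 0.0
    for fi in fids:
        ar = face_ars[fi]
        if math.isinf(ar):
            return UNDEFINED
        total += ar
    return total / len(fids)


def improve_aspect_ratios(mesh: TriangleMesh, passes: int = 3,
                          reference: TriangleMesh | None = None) -> TriangleMesh:
    """Run the guarded relocation sweep ``passes`` times; returns a mesh
    with the same faces and improved vertex positions."""
    if reference is None:
        reference = mesh
    projector = MeshProjector(reference.vertices, reference.faces)

    V = mesh.vertices.copy()
    F = mesh.faces
    vfaces = mesh.vertex_faces
    n = len(V)

    # valence-derived face weights for the monotonicity guard:
    # w_t = sum over the 3 corners of 1 / (number of faces at that corner)
    w_face = np.zeros(len(F))
    for fi, tri in enumerate(F):
        w_face[fi] = sum(1.0 / len(vfaces[int(x)]) for x in tri)

    for _ in range(passes):
        work = TriangleMesh(V, F, validate=False)
        # Jacobi-style candidate positions (computed from the pass-start
        # geometry), batch-projected to the reference surface; acceptance
        # below is sequential against the live positions
        cand_cvt = np.empty((n, 3))
        cand_lap = np.empty((n, 3))
        movable = np.ones(n, dtype=bool)
        for vid in range(n):
            try:
                cand_cvt[vid] = cvt_centroid(work, vid)
                cand_lap[vid] = laplacian_center(work, vid)
            except DegenerateRingError:
                movable[vid] = False
                cand_cvt[vid] = V[vid]
                cand_lap[vid] = V[vid]
        cand_cvt[movable] = projector.project(cand_cvt[movable])
        cand_lap[movable] = projector.project(cand_lap[movable])

        face_ars = {fi: _face_ar(V, tri) for fi, tri in enumerate(F)}

        for vid in range(n):
            if not movable[vid]:
                continue
            fids = vfaces[vid]
            ar_old = _vertex_ar_from(face_ars, fids)
            old_pos = V[vid].copy()
            for cand in (cand_cvt[vid], cand_lap[vid]):
                if not np.isfinite(cand).all():
                    continue
                V[vid] = cand
                new_ars = {fi: _face_ar(V, F[fi]) for fi in fids}
                ar_new = _vertex_ar_from({**face_ars, **new_ars}, fids)
                if not ar_new < ar_old:
                    V[vid] = old_pos
                    continue
                # guards: no finite AR may become undefined; the weighted
                # finite-AR sum must not increase; no normal flip
                ok = True
                delta = 0.0
                for fi in fids:
                    a0, a1 = face_ars[fi], new_ars[fi]
                    if math.isinf(a1) and not math.isinf(a0):
                        ok = False
                        break
                    if not math.isinf(a0) and not math.isinf(a1):
                        delta += w_face[fi] * (a1 - a0)
                if ok and delta > 0.0:
                    ok = False
                if ok:
                    V[vid] = old_pos
                    for fi in fids:
                        tri = F[fi]
                        p_old = [V[int(x)] for x in tri]
                        p_new = [cand if int(x) == vid else V[int(x)] for x in tri]
                        n_old = np.cross(p_old[1] - p_old[0], p_old[2] - p_old[0])
                        n_new = np.cross(p_new[1] - p_new[0], p_new[2] - p_new[0])
                        if float(np.dot(n_old, n_new)) <= 0.0 and float(np.dot(n_old, n_old)) > 0.0:
                            ok = False
                            break
                if not ok:
                    V[vid] = old_pos
                    continue
                V[vid] = cand
                face_ars.update(new_ars)
                break

    return TriangleMesh(V, F.copy(), validate=False)
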