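"""Low-level triangle geometry kernels.

Scalar helpers (plain ``math`` on 3-tuples) are used inside the local
remeshing operators where per-call numpy overhead dominates; vectorized
variants serve the whole-mesh quality metrics.  The triangle–triangle
intersection predicate and the closest-point projector live here because
both the metrics and the repair stage need them.

All predicates are floating point with relative tolerances; exact
arithmetic is out of scope.
"""
from __future__ import annotations

import math

import numpy as np
from scipy.spatial import cKDTree

#: sentinel for undefined aspect ratios; compares worse than any finite value
UNDEFINED = math.inf

#: a triangle is degenerate when area < DEGENERATE_AREA_FACTOR * h^2 (h = longest edge)
DEGENERATE_AREA_FACTOR = 1e-12


# ---------------------------------------------------------------------------
# scalar kernels
# ---------------------------------------------------------------------------

def edge_lengths(p0, p1, p2):
    """Side lengths (a, b, c) opposite vertices p0, p1, p2."""
    a = math.dist(p1, p2)
    b = math.dist(p0, p2)
    c = math.dist(p0, p1)
    return a, b, c


def triangle_area_3d(p0, p1, p2) -> float:
    ux, uy, uz = p1[0] - p0[0], p1[1] - p0[1], p1[2] - p0[2]
    vx, vy, vz = p2[0] - p0[0], p2[1] - p0[1], p2[2] - p0[2]
    cx = uy * vz - uz * vy
    cy = uz * vx - ux * vz
    cz = ux * vy - uy * vx
    return 0.5 * math.sqrt(cx * cx + cy * cy + cz * cz)


def triangle_normal(p0, p1, p2):
    """Unnormalized CCW normal as a 3-tuple."""
    ux, uy, uz = p1[0] - p0[0], p1[1] - p0[1], p1[2] - p0[2]
    vx, vy, vz = p2[0] - p0[0], p2[1] - p0[1], p2[2] - p0[2]
    return (uy * vz - uz * vy, uz * vx - ux * vz, ux * vy - uy * vx)


def is_degenerate(p0, p1, p2) -> bool:
    a, b, c = edge_lengths(p0, p1, p2)
    h = max(a, b, c)
    if h == 0.0:
        return True
    return triangle_area_3d(p0, p1, p2) < DEGENERATE_AREA_FACTOR * h * h


def angles_deg(p0, p1, p2):
    """Interior angles in degrees at (p0, p1, p2) via the law of cosines.

    Raises ValueError on a zero-length edge.
    """
    a, b, c = edge_lengths(p0, p1, p2)  # a opposite p0 etc.
    if a == 0.0 or b == 0.0 or c == 0.0:
        raise ValueError("zero-length edge")
    ca = (b * b + c * c - a * a) / (2.0 * b * c)
    cb = (a * a + c * c - b * b) / (2.0 * a * c)
    ca = min(1.0, max(-1.0, ca))
    cb = min(1.0, max(-1.0, cb))
    A = math.degrees(math.acos(ca))
    B = math.degrees(math.acos(cb))
    return A, B, 180.0 - A - B


def min_angle_deg(p0, p1, p2) -> float:
    try:
        return min(angles_deg(p0, p1, p2))
    except ValueError:
        return 0.0


def quality_scalar(p0, p1, p2) -> float:
    """Q(t) = (6/sqrt(3)) * A / (p * h); 1 for equilateral, 0 when degenerate."""
    a, b, c = edge_lengths(p0, p1, p2)
    h = max(a, b, c)
    if h == 0.0:
        return 0.0
    area = triangle_area_3d(p0, p1, p2)
    if area < DEGENERATE_AREA_FACTOR * h * h:
        return 0.0
    p = 0.5 * (a + b + c)
    return (6.0 / math.sqrt(3.0)) * area / (p * h)


def aspect_ratio_scalar(p0, p1, p2) -> float:
    """AR(t) = abc / (8 (S-a)(S-b)(S-c)); UNDEFINED when degenerate."""
    a, b, c = edge_lengths(p0, p1, p2)
    h = max(a, b, c)
    if h == 0.0:
        return UNDEFINED
    if triangle_area_3d(p0, p1, p2) < DEGENERATE_AREA_FACTOR * h * h:
        return UNDEFINED
    S = 0.5 * (a + b + c)
    denom = 8.0 * (S - a) * (S - b) * (S - c)
    if denom <= 0.0:
        return UNDEFINED
    return a * b * c / denom


# ---------------------------------------------------------------------------
# vectorized kernels (whole-mesh metrics)
# ---------------------------------------------------------------------------

def face_corner_coords(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """(m, 3, 3) array of corner coordinates."""
    return vertices[faces]


def face_edge_lengths(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """(m, 3) side lengths, column j opposite corner j."""
    P = vertices[faces]
    a = np.linalg.norm(P[:, 1] - P[:, 2], axis=1)
    b = np.linalg.norm(P[:, 0] - P[:, 2], axis=1)
    c = np.linalg.norm(P[:, 0] - P[:, 1], axis=1)
    return np.stack([a, b, c], axis=1)


def face_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    P = vertices[faces]
    n = np.cross(P[:, 1] - P[:, 0], P[:, 2] - P[:, 0])
    return 0.5 * np.linalg.norm(n, axis=1)


def face_angles_deg(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """(m, 3) interior angles in degrees; degenerate corners yield 0 or 180."""
    L = face_edge_lengths(vertices, faces)
    a, b, c = L[:, 0], L[:, 1], L[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        ca = (b * b + c * c - a * a) / (2 * b * c)
        cb = (a * a + c * c - b * b) / (2 * a * c)
        cc = (a * a + b * b - c * c) / (2 * a * b)
    cos = np.stack([ca, cb, cc], axis=1)
    cos = np.clip(np.nan_to_num(cos, nan=1.0), -1.0, 1.0)
    return np.degrees(np.arccos(cos))


def face_qualities(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    L = face_edge_lengths(vertices, faces)
    h = L.max(axis=1)
    p = 0.5 * L.sum(axis=1)
    A = face_areas(vertices, faces)
    q = np.zeros(len(faces))
    ok = (h > 0) & (A >= DEGENERATE_AREA_FACTOR * h * h)
    q[ok] = (6.0 / math.sqrt(3.0)) * A[ok] / (p[ok] * h[ok])
    return q


def face_aspect_ratios(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """(m,) aspect ratios; UNDEFINED (inf) for degenerate triangles."""
    L = face_edge_lengths(vertices, faces)
    a, b, c = L[:, 0], L[:, 1], L[:, 2]
    h = L.max(axis=1)
    A = face_areas(vertices, faces)
    S = 0.5 * (a + b + c)
    denom = 8.0 * (S - a) * (S - b) * (S - c)
    ar = np.full(len(faces), UNDEFINED)
    ok = (h > 0) & (A >= DEGENERATE_AREA_FACTOR * h * h) & (denom > 0)
    ar[ok] = (a * b * c)[ok] / denom[ok]
    return ar


# ---------------------------------------------------------------------------
# triangle–triangle intersection
# ---------------------------------------------------------------------------

def _plane_interval(proj, dist, eps):
    """Projection interval of a triangle's plane-crossing segment.

    proj: scalar projections of the 3 vertices onto the intersection line
    direction; dist: snapped signed distances to the other plane.
    Returns (lo, hi) or None when the triangle does not reach the plane.
    """
    pts = []
    for i, j in ((0, 1), (1, 2), (2, 0)):
        if dist[i] == 0.0:
            pts.append(proj[i])
        if dist[i] * dist[j] < 0.0:
            t = dist[i] / (dist[i] - dist[j])
            pts.append(proj[i] + t * (proj[j] - proj[i]))
    if not pts:
        return None
    return min(pts), max(pts)


def _coplanar_overlap(V, U, normal, scale) -> bool:
    from shapely.geometry import Polygon

    ax = int(np.argmax(np.abs(normal)))
    keep = [i for i in range(3) if i != ax]
    try:
        p1 = Polygon(V[:, keep])
        p2 = Polygon(U[:, keep])
    except Exception:
        return False
    if not (p1.is_valid and p2.is_valid):
        return False
    inter = p1.intersection(p2)
    return inter.area > 1e-12 * scale * scale


def tri_tri_intersect(V: np.ndarray, U: np.ndarray) -> bool:
    """Exact-within-tolerance test whether two closed triangles intersect.

    Non-coplanar pairs use plane-interval overlap on the intersection line
    (Moller-style); coplanar pairs count when the 2D overlap has positive
    area.  Zero-area triangles have no interior and never intersect.
    Grazing contact within ~1e-9 of the local scale is not counted.
    """
    V = np.asarray(V, dtype=float)
    U = np.asarray(U, dtype=float)
    scale = max(
        np.linalg.norm(V[1] - V[0]), np.linalg.norm(V[2] - V[0]),
        np.linalg.norm(U[1] - U[0]), np.linalg.norm(U[2] - U[0]),
    )
    if scale == 0.0:
        return False
    eps = 1e-9 * scale

    n2 = np.cross(U[1] - U[0], U[2] - U[0])
    l2 = np.linalg.norm(n2)
    n1 = np.cross(V[1] - V[0], V[2] - V[0])
    l1 = np.linalg.norm(n1)
    if l1 < DEGENERATE_AREA_FACTOR * scale * scale or \
       l2 < DEGENERATE_AREA_FACTOR * scale * scale:
        return False  # degenerate: no interior
    n1 /= l1
    n2 /= l2

    dv = (V - U[0]) @ n2
    dv[np.abs(dv) < eps] = 0.0
    if np.all(dv > 0) or np.all(dv < 0):
        return False
    du = (U - V[0]) @ n1
    du[np.abs(du) < eps] = 0.0
    if np.all(du > 0) or np.all(du < 0):
        return False

    if np.all(dv == 0.0) and np.all(du == 0.0):
        return _coplanar_overlap(V, U, n1, scale)

    D = np.cross(n1, n2)
    nd = np.linalg.norm(D)
    if nd < 1e-12:
        # numerically parallel but not snapped coplanar: treat as coplanar
        return _coplanar_overlap(V, U, n1, scale)
    D /= nd

    iv = _plane_interval(V @ D, dv, eps)
    iu = _plane_interval(U @ D, du, eps)
    if iv is None or iu is None:
        return False
    lo = max(iv[0], iu[0])
    hi = min(iv[1], iu[1])
    return hi - lo > eps


# ---------------------------------------------------------------------------
# closest point on a triangle mesh (reference-surface projection)
# ---------------------------------------------------------------------------

def closest_points_on_triangles(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Closest point on each triangle to each point (paired, vectorized).

    points: (n, 3); tris: (n, 3, 3).  The optimum is the in-plane projection
    when its barycentric coordinates are non-negative, otherwise the best of
    the three clamped edge projections.
    """
    p = np.asarray(points, dtype=float)
    A, B, C = tris[:, 0], tris[:, 1], tris[:, 2]

    cands = []
    dists = []

    # interior projection via barycentric coordinates
    ab = B - A
    ac = C - A
    n = np.cross(ab, ac)
    nn = np.einsum("ij,ij->i", n, n)
    nn_safe = np.where(nn > 0, nn, 1.0)
    ap = p - A
    t = np.einsum("ij,ij->i", ap, n) / nn_safe
    proj = p - t[:, None] * n
    # barycentric of proj
    vp = proj - A
    d00 = np.einsum("ij,ij->i", ab, ab)
    d01 = np.einsum("ij,ij->i", ab, ac)
    d11 = np.einsum("ij,ij->i", ac, ac)
    d20 = np.einsum("ij,ij->i", vp, ab)
    d21 = np.einsum("ij,ij->i", vp, ac)
    den = d00 * d11 - d01 * d01
    den_safe = np.where(np.abs(den) > 0, den, 1.0)
    v = (d11 * d20 - d01 * d21) / den_safe
    w = (d00 * d21 - d01 * d20) / den_safe
    inside = (v >= 0) & (w >= 0) & (v + w <= 1) & (nn > 0) & (np.abs(den) > 0)
    d_int = np.where(inside, np.linalg.norm(p - proj, axis=1), np.inf)
    cands.append(proj)
    dists.append(d_int)

    for a, b in ((A, B), (B, C), (C, A)):
        e = b - a
        ee = np.einsum("ij,ij->i", e, e)
        ee_safe = np.where(ee > 0, ee, 1.0)
        s = np.clip(np.einsum("ij,ij->i", p - a, e) / ee_safe, 0.0, 1.0)
        q = a + s[:, None] * e
        cands.append(q)
        dists.append(np.linalg.norm(p - q, axis=1))

    dists = np.stack(dists, axis=0)       # (4, n)
    cands = np.stack(cands, axis=0)       # (4, n, 3)
    best = np.argmin(dists, axis=0)
    return cands[best, np.arange(len(p))]


class MeshProjector:
    """Closest-point queries against a fixed reference triangle mesh.

    Broad phase: k-nearest triangle centroids from a cKDTree, with an exact
    ball-query fallback whenever the k-NN candidate set cannot certify the
    optimum (best distance exceeds the k-th centroid distance minus the
    largest triangle bounding radius).
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray, k: int = 16):
        tris = np.asarray(vertices, dtype=float)[np.asarray(faces)]
        centroids = tris.mean(axis=1)
        radii = np.linalg.norm(tris - centroids[:, None, :], axis=2).max(axis=1)
        # oversized triangles (narrow bridges and the like) would wreck the
        # k-NN certification bound; they are few, so test them exhaustively
        cutoff = 4.0 * float(np.median(radii)) if len(radii) else 0.0
        big = radii > cutoff
        self.big_tris = tris[big]
        self.tris = tris[~big]
        if len(self.tris) == 0:  # degenerate split: keep everything k-NN side
            self.tris = tris
            self.big_tris = tris[:0]
        self.centroids = self.tris.mean(axis=1)
        self.radii = np.linalg.norm(
            self.tris - self.centroids[:, None, :], axis=2
        ).max(axis=1)
        self.rmax = float(self.radii.max()) if len(self.radii) else 0.0
        self.tree = cKDTree(self.centroids)
        self.k = min(k, len(self.tris))

    def project(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        dcent, idx = self.tree.query(points, k=self.k)
        if self.k == 1:
            dcent = dcent[:, None]
            idx = idx[:, None]
        n, k = idx.shape
        flat_pts = np.repeat(points, k, axis=0)
        flat_tris = self.tris[idx.ravel()]
        cp = closest_points_on_triangles(flat_pts, flat_tris).reshape(n, k, 3)
        d = np.linalg.norm(cp - points[:, None, :], axis=2)
        best = np.argmin(d, axis=1)
        out = cp[np.arange(n), best]
        dbest = d[np.arange(n), best]

        # certification: optimum is guaranteed among candidates only if
        # dbest <= dcent_k - rmax
        need = dbest > dcent[:, -1] - self.rmax
        for i in np.nonzero(need)[0]:
            cand = self.tree.query_ball_point(points[i], dbest[i] + self.rmax + 1e-12)
            if not cand:
                continue
            cand = np.asarray(cand)
            cps = closest_points_on_triangles(
                np.repeat(points[i][None], len(cand), axis=0), self.tris[cand]
            )
            dd = np.linalg.norm(cps - points[i], axis=1)
            j = int(np.argmin(dd))
            if dd[j] < dbest[i]:
                out[i] = cps[j]

        if len(self.big_tris):
            nb = len(self.big_tris)
            flat_pts = np.repeat(points, nb, axis=0)
            flat_tris = np.tile(self.big_tris, (n, 1, 1))
            cps = closest_points_on_triangles(flat_pts, flat_tris).reshape(n, nb, 3)
            dd = np.linalg.norm(cps - points[:, None, :], axis=2)
            jb = np.argmin(dd, axis=1)
            db = dd[np.arange(n), jb]
            better = db < dbest
            out[better] = cps[np.arange(n), jb][better]
        return out

    def project_one(self, point) -> np.ndarray:
        return self.project(np.asarray(point, dtype=float)[None])[0]
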