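"""Curvature-adaptive isotropic remeshing initialization.

The raw mesh is first driven toward a curvature-adaptive target edge
length: per-vertex sizing

    L(v) = sqrt(max(6 eps / kappa - 3 eps^2, 0)),   L(e) = min endpoint L,

where kappa = H + sqrt(max(H^2 - K, 0)) is the maximum absolute
curvature from the discrete mean curvature H (cotangent Laplacian,
mixed-Voronoi normalization) and Gaussian curvature K (angle deficit
(2 pi - sum theta) / A_mixed).  Each iteration then

1. splits edges longer than (4/3) L(e) at their midpoints,
2. collapses edges shorter than (4/5) L(e) to their midpoints (guarded:
   link condition, no over-long new edges, no normal flips),
3. flips edges when the flip reduces the squared valence deviation
   from 6,
4. relaxes every vertex tangentially toward its one-ring mean, and
5. projects vertices back to the reference surface (the raw input by
   default), which keeps area and volume near the input.

Since the sizing formula diverges as kappa -> 0, L is clamped to
[0.1, 3] x the input mean edge length.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _geometry as geom
from ._edit import EditableMesh
from ._geometry import MeshProjector
from .errors import CurvatureUndefinedError, NonManifoldError
from .mesh_core import TriangleMesh

__all__ = [
    "CurvatureEstimate",
    "SizingField",
    "discrete_curvatures",
    "all_curvatures",
    "sizing_field",
    "rar_remesh",
]


@dataclass
class CurvatureEstimate:
    """Discrete curvatures at a vertex: H (1/A), K (1/A^2), kappa =
    H + sqrt(max(H^2 - K, 0)) (1/A), mixed Voronoi area (A^2), and the
    incident angle sum (radians)."""

    mean_h: float
    gaussian_k: float
    kappa: float
    voronoi_area: float
    angle_sum: float


@dataclass
class SizingField:
    """Per-vertex target edge lengths with their clamp bounds."""

    vertex_length: np.ndarray
    epsilon: float
    l_min: float
    l_max: float

    def edge_length(self, u: int, v: int) -> float:
        return float(min(self.vertex_length[u], self.vertex_length[v]))


def _mixed_area_and_curvature(mesh: TriangleMesh):
    """Vectorized Meyer-style mixed Voronoi areas, angle sums, and the
    cotangent mean-curvature vector accumulator for every vertex.

    Returns (A_mixed, angle_sum, lap) where lap[i] = sum_j (cot a + cot b)
    (v_i - v_j) over the one-ring, before the 1/(2A) normalization.
    """
    V = mesh.vertices
    F = mesh.faces
    n = len(V)
    P = V[F]
    ang = np.radians(geom.face_angles_deg(V, F))  # (m, 3)
    with np.errstate(divide="ignore", invalid="ignore"):
        cot = 1.0 / np.tan(ang)
    cot = np.nan_to_num(cot, nan=0.0, posinf=0.0, neginf=0.0)
    areas = geom.face_areas(V, F)

    A = np.zeros(n)
    angle_sum = np.zeros(n)
    lap = np.zeros((n, 3))

    # edge vectors opposite each corner: corner 0 faces edge (1,2) etc.
    idx_opp = [(1, 2), (2, 0), (0, 1)]
    obtuse = ang > (math.pi / 2)
    any_obtuse = obtuse.any(axis=1)

    for corner in range(3):
        i = F[:, corner]
        np.add.at(angle_sum, i, ang[:, corner])
        # Voronoi (non-obtuse triangles): (1/8)(|e_q|^2 cot q + |e_r|^2 cot r)
        # where q, r are the two other corners and e_x the edge from this
        # vertex to the corner x
        q, r = [c for c in range(3) if c != corner]
        e_q = np.linalg.norm(P[:, corner] - P[:, q], axis=1)
        e_r = np.linalg.norm(P[:, corner] - P[:, r], axis=1)
        # angle at r is opposite edge (corner, q); angle at q opposite (corner, r)
        voro = 0.125 * (e_q**2 * cot[:, r] + e_r**2 * cot[:, q])
        contrib = np.where(
            any_obtuse,
            np.where(obtuse[:, corner], areas / 2.0, areas / 4.0),
            voro,
        )
        np.add.at(A, i, contrib)

    # cotangent accumulation: corner k (angle alpha_k) is opposite edge (i, j);
    # it contributes cot(alpha_k) * (v_i - v_j) to lap[i] and the negative to lap[j]
    for corner in range(3):
        i = F[:, idx_opp[corner][0]]
        j = F[:, idx_opp[corner][1]]
        w = cot[:, corner][:, None]
        d = (V[i] - V[j]) * w
        np.add.at(lap, i, d)
        np.add.at(lap, j, -d)

    return A, angle_sum, lap


def all_curvatures(mesh: TriangleMesh) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-vertex (H, K, kappa, A_mixed, angle_sum) arrays.

    Vertices with a degenerate one-ring (A ~ 0) get NaN curvatures; the
    sizing field substitutes the neighbor average for those.
    """
    A, angle_sum, lap = _mixed_area_and_curvature(mesh)
    scale = float(np.mean(geom.face_areas(mesh.vertices, mesh.faces))) if mesh.n_faces else 1.0
    tiny = 1e-12 * max(scale, 1e-30)
    ok = A > tiny
    H = np.full(len(A), np.nan)
    K = np.full(len(A), np.nan)
    H[ok] = 0.5 * np.linalg.norm(lap[ok] / (2.0 * A[ok, None]), axis=1)
    K[ok] = (2.0 * math.pi - angle_sum[ok]) / A[ok]
    kappa = H + np.sqrt(np.maximum(H * H - K, 0.0))
    return H, K, kappa, A, angle_sum


def discrete_curvatures(mesh: TriangleMesh, vertex: int) -> CurvatureEstimate:
    """Curvature estimate at one vertex (see module docstring for the
    discretization).  Raises CurvatureUndefinedError on a degenerate
    one-ring; callers typically substitute a neighbor average."""
    H, K, kappa, A, angle_sum = all_curvatures(mesh)
    if math.isnan(H[vertex]):
        raise CurvatureUndefinedError(f"vertex {vertex} has a degenerate one-ring")
    return CurvatureEstimate(
        mean_h=float(H[vertex]),
        gaussian_k=float(K[vertex]),
        kappa=float(kappa[vertex]),
        voronoi_area=float(A[vertex]),
        angle_sum=float(angle_sum[vertex]),
    )


def sizing_field(mesh: TriangleMesh, epsilon: float,
                 l_min: float | None = None, l_max: float | None = None,
                 smoothing_passes: int = 0) -> SizingField:
    """Curvature-adaptive target edge lengths, clamped to [l_min, l_max]
    (defaults 0.1x and 3x the mean edge length).

    ``smoothing_passes`` neighbor-averaging sweeps grade the field; raw
    meshes have spiky curvature estimates at defects, and an unsmoothed
    field would lock their tiny target lengths in place."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    E = mesh.edges_unique
    mean_edge = float(np.linalg.norm(
        mesh.vertices[E[:, 0]] - mesh.vertices[E[:, 1]], axis=1
    ).mean()) if len(E) else 1.0
    if l_min is None:
        l_min = 0.1 * mean_edge
    if l_max is None:
        l_max = 3.0 * mean_edge

    _, _, kappa, _, _ = all_curvatures(mesh)
    bad = ~np.isfinite(kappa)
    if bad.any():
        # substitute neighbor averages, then the global mean
        fill = kappa.copy()
        glob = float(np.nanmean(kappa)) if np.isfinite(np.nanmean(kappa)) else 0.0
        adj = [[] for _ in range(mesh.n_vertices)]
        for u, v in E:
            adj[u].append(v)
            adj[v].append(u)
        for i in np.nonzero(bad)[0]:
            vals = [kappa[j] for j in adj[i] if np.isfinite(kappa[j])]
            fill[i] = float(np.mean(vals)) if vals else glob
        kappa = fill

    with np.errstate(divide="ignore", invalid="ignore"):
        L2 = 6.0 * epsilon / kappa - 3.0 * epsilon * epsilon
    L = np.sqrt(np.maximum(np.nan_to_num(L2, nan=0.0, posinf=np.inf), 0.0))
    L[kappa <= 0] = l_max  # flat or saddle-dominated: clamp handles it
    L = np.clip(L, l_min, l_max)
    if smoothing_passes > 0 and len(E):
        for _ in range(smoothing_passes):
            acc = L.copy()
            deg = np.ones(len(L))
            np.add.at(acc, E[:, 0], L[E[:, 1]])
            np.add.at(acc, E[:, 1], L[E[:, 0]])
            np.add.at(deg, E[:, 0], 1)
            np.add.at(deg, E[:, 1], 1)
            L = acc / deg
        L = np.clip(L, l_min, l_max)
    return SizingField(vertex_length=L, epsilon=float(epsilon),
                       l_min=float(l_min), l_max=float(l_max))


# ---------------------------------------------------------------------------
# remeshing loop
# ---------------------------------------------------------------------------

def _split_pass(em: EditableMesh, L: dict[int, float]) -> int:
    from collections import deque

    queue = deque(sorted(em.edges()))
    count = 0
    while queue:
        u, v = queue.popleft()
        if u not in em.V or v not in em.V or not em.has_edge(u, v):
            continue
        target = min(L[u], L[v])
        if em.edge_length(u, v) <= (4.0 / 3.0) * target:
            continue
        fids = em.faces_of_edge(u, v)
        if len(fids) == 2 and set(em.F[fids[0]]) == set(em.F[fids[1]]):
            continue  # degenerate pillow pair
        mid = 0.5 * (em.V[u] + em.V[v])
        m, _ = em.split_edge(u, v, mid)
        L[m] = 0.5 * (L[u] + L[v])
        count += 1
        for n in em.vertex_neighbors(m):
            queue.append((m, n) if m < n else (n, m))
    return count


def _collapse_pass(em: EditableMesh, L: dict[int, float]) -> int:
    count = 0
    for u, v in sorted(em.edges()):
        if u not in em.V or v not in em.V or not em.has_edge(u, v):
            continue
        target = min(L[u], L[v])
        if em.edge_length(u, v) >= (4.0 / 5.0) * target:
            continue
        if not em.can_collapse(u, v):
            continue
        mid = 0.5 * (em.V[u] + em.V[v])
        # guard: no surviving edge at the merged vertex may exceed (4/3) L
        too_long = False
        merged_L = 0.5 * (L[u] + L[v])
        for w in (em.vertex_neighbors(u) | em.vertex_neighbors(v)) - {u, v}:
            if float(np.linalg.norm(mid - em.V[w])) > (4.0 / 3.0) * min(merged_L, L.get(w, merged_L)):
                too_long = True
                break
        if too_long:
            continue
        shared = set(em.faces_of_edge(u, v))
        if em.would_flip_normal(u, mid, exclude=shared) or \
           em.would_flip_normal(v, mid, exclude=shared):
            continue
        if em.collapse_edge(u, v, mid):
            L[u] = merged_L
            L.pop(v, None)
            count += 1
    return count


def _flip_pass(em: EditableMesh) -> int:
    def valence(v):
        return len(em.vertex_neighbors(v))

    count = 0
    for u, v in sorted(em.edges()):
        if u not in em.V or v not in em.V:
            continue
        fids = em.faces_of_edge(u, v)
        if len(fids) != 2:
            continue
        a = em.opposite_vertex(fids[0], u, v)
        b = em.opposite_vertex(fids[1], u, v)
        if a == b or em.has_edge(a, b):
            continue
        before = sum((valence(x) - 6) ** 2 for x in (u, v, a, b))
        after = ((valence(u) - 7) ** 2 + (valence(v) - 7) ** 2
                 + (valence(a) - 5) ** 2 + (valence(b) - 5) ** 2)
        if after >= before:
            continue
        # geometric guard: both new faces must keep the local orientation
        n_old = em.face_normal(fids[0]) + em.face_normal(fids[1])
        n_new1 = np.cross(em.V[b] - em.V[u], em.V[a] - em.V[u])
        n_new2 = np.cross(em.V[a] - em.V[v], em.V[b] - em.V[v])
        if np.dot(n_old, n_new1) <= 0 or np.dot(n_old, n_new2) <= 0:
            continue
        if em.flip_edge(u, v):
            count += 1
    return count


def _relax_and_project(mesh: TriangleMesh, projector: MeshProjector) -> TriangleMesh:
    """Tangential Laplacian relaxation (Jacobi step) + reference projection."""
    V = mesh.vertices
    F = mesh.faces
    n = len(V)
    # one-ring means via the edge adjacency
    E = mesh.edges_unique
    acc = np.zeros((n, 3))
    deg = np.zeros(n)
    np.add.at(acc, E[:, 0], V[E[:, 1]])
    np.add.at(acc, E[:, 1], V[E[:, 0]])
    np.add.at(deg, E[:, 0], 1)
    np.add.at(deg, E[:, 1], 1)
    deg[deg == 0] = 1
    centers = acc / deg[:, None]

    # area-weighted vertex normals
    fn = np.cross(V[F[:, 1]] - V[F[:, 0]], V[F[:, 2]] - V[F[:, 0]])
    vn = np.zeros((n, 3))
    for c in range(3):
        np.add.at(vn, F[:, c], fn)
    norms = np.linalg.norm(vn, axis=1)
    norms[norms == 0] = 1.0
    vn /= norms[:, None]

    delta = centers - V
    tangential = delta - (np.einsum("ij,ij->i", delta, vn))[:, None] * vn
    moved = V + tangential
    projected = projector.project(moved)
    return TriangleMesh(projected, F.copy(), validate=False)


def rar_remesh(mesh: TriangleMesh, epsilon: float | None = None,
               iterations: int = 5,
               reference: TriangleMesh | None = None) -> TriangleMesh:
    """Adaptive split/collapse/flip/relax remeshing toward the sizing field.

    ``epsilon`` defaults to 0.002 x the bounding-box diagonal;
    ``reference`` (projection target) defaults to the input mesh itself.
    Genus and closedness are preserved.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if not mesh.is_edge_manifold:
        raise NonManifoldError("rar_remesh requires an edge-manifold input")
    if epsilon is None:
        bbox = mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0)
        epsilon = 0.002 * float(np.linalg.norm(bbox))
    if reference is None:
        reference = mesh
    projector = MeshProjector(reference.vertices, reference.faces)

    # clamp bounds are fixed from the *input* mean edge length so the
    # target does not drift as the mesh is refined
    E0 = mesh.edges_unique
    mean_edge0 = float(np.linalg.norm(
        mesh.vertices[E0[:, 0]] - mesh.vertices[E0[:, 1]], axis=1).mean())
    l_min, l_max = 0.1 * mean_edge0, 3.0 * mean_edge0

    current = mesh
    for _ in range(iterations):
        field = sizing_field(current, epsilon, l_min=l_min, l_max=l_max,
                             smoothing_passes=2)
        em = EditableMesh.from_mesh(current)
        L = {i: float(field.vertex_length[i]) for i in range(current.n_vertices)}
        _split_pass(em, L)
        _flip_pass(em)
        _collapse_pass(em, L)
        _flip_pass(em)
        compact, _, _ = em.to_mesh()
        current = compact
        for _relax in range(3):
            current = _relax_and_project(current, projector)
    current._validate()
    return current
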