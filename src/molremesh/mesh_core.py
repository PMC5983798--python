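"""Triangle mesh container, standard-format I/O, and quality metrics.

The :class:`TriangleMesh` is an indexed vertex/face array pair with lazily
built edge-manifold connectivity.  It is treated as immutable: every
remeshing stage returns a new instance.  Metrics follow the conventions
used for molecular surface mesh benchmarks:

* triangle quality  Q(t) = (6/sqrt(3)) * A_t / (p_t * h_t)   (p = half
  perimeter, h = longest edge; 1 for equilateral, 0 for degenerate)
* aspect ratio      AR(t) = abc / (8 (S-a)(S-b)(S-c))        (S = half
  perimeter; 1 for equilateral, undefined for degenerate triangles)
* Euler number      E = n_v + n_f - n_e,  genus = 1 - E/2 for closed
  surfaces (an internal cavity contributes -1)
* regular vertices: valence 5-7 for interior vertices, 3-5 for boundary
  vertices, as a percentage of all vertices
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np

from . import _geometry as geom
from ._geometry import UNDEFINED
from .errors import (
    DegenerateFaceError,
    IsolatedVertexError,
    MeshFormatError,
    NonManifoldError,
    NotClosedError,
    UnsupportedElementError,
)

__all__ = [
    "TriangleMesh",
    "QualityReport",
    "IntersectionPair",
    "UNDEFINED",
    "read_mesh",
    "write_mesh",
    "triangle_angles",
    "triangle_quality",
    "triangle_aspect_ratio",
    "vertex_aspect_ratio",
    "euler_number",
    "genus",
    "surface_area",
    "enclosed_volume",
    "regular_vertex_ratio",
    "self_intersections",
    "self_intersections_brute_force",
    "quality_report",
]


class TriangleMesh:
    """Indexed triangle surface mesh (coordinates in Angstrom).

    Faces are stored counter-clockwise viewed from outside (outward
    normals).  Construction validates that every face references three
    distinct in-range vertices and that every edge has at most two
    incident faces (edge-manifold).  Duplicate vertex coordinates are
    retained — raw molecular meshes keep their redundancy until an
    explicit weld.
    """

    def __init__(self, vertices, faces, validate: bool = True):
        self.vertices = np.ascontiguousarray(np.asarray(vertices, dtype=np.float64))
        self.faces = np.ascontiguousarray(np.asarray(faces, dtype=np.int64))
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.size == 0:
            self.faces = self.faces.reshape(0, 3)
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        self._cache: dict = {}
        if validate:
            self._validate()

    # -- construction / validation ---------------------------------------

    def _validate(self) -> None:
        f = self.faces
        if len(f):
            if f.min() < 0 or f.max() >= len(self.vertices):
                raise ValueError("face references out-of-range vertex index")
            same = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
            if same.any():
                bad = int(np.nonzero(same)[0][0])
                raise ValueError(f"face {bad} repeats a vertex index")
        counts = self.edge_face_counts
        if len(counts) and counts.max() > 2:
            e = self.edges_unique[int(np.argmax(counts))]
            raise NonManifoldError(f"edge {tuple(e)} has {counts.max()} incident faces")

    # -- connectivity (lazy) ----------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def n_edges(self) -> int:
        return len(self.edges_unique)

    @property
    def edges_unique(self) -> np.ndarray:
        """(e, 2) sorted unique undirected edges."""
        if "edges" not in self._cache:
            self._build_edges()
        return self._cache["edges"]

    @property
    def edge_face_counts(self) -> np.ndarray:
        if "edge_counts" not in self._cache:
            self._build_edges()
        return self._cache["edge_counts"]

    def _build_edges(self) -> None:
        f = self.faces
        if len(f) == 0:
            self._cache["edges"] = np.zeros((0, 2), dtype=np.int64)
            self._cache["edge_counts"] = np.zeros(0, dtype=np.int64)
            return
        e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        e = np.sort(e, axis=1)
        edges, counts = np.unique(e, axis=0, return_counts=True)
        self._cache["edges"] = edges
        self._cache["edge_counts"] = counts

    @property
    def boundary_edges(self) -> np.ndarray:
        """Edges with exactly one incident face."""
        return self.edges_unique[self.edge_face_counts == 1]

    @property
    def is_closed(self) -> bool:
        return self.n_faces > 0 and bool((self.edge_face_counts == 2).all())

    @property
    def is_edge_manifold(self) -> bool:
        return len(self.edge_face_counts) == 0 or self.edge_face_counts.max() <= 2

    @property
    def vertex_faces(self) -> list[list[int]]:
        """Per-vertex list of incident face indices."""
        if "vertex_faces" not in self._cache:
            vf: list[list[int]] = [[] for _ in range(self.n_vertices)]
            for fi, (a, b, c) in enumerate(self.faces):
                vf[a].append(fi)
                vf[b].append(fi)
                vf[c].append(fi)
            self._cache["vertex_faces"] = vf
        return self._cache["vertex_faces"]

    @property
    def vertex_valence(self) -> np.ndarray:
        if "valence" not in self._cache:
            val = np.zeros(self.n_vertices, dtype=np.int64)
            e = self.edges_unique
            np.add.at(val, e[:, 0], 1)
            np.add.at(val, e[:, 1], 1)
            self._cache["valence"] = val
        return self._cache["valence"]

    @property
    def boundary_vertex_mask(self) -> np.ndarray:
        if "boundary_mask" not in self._cache:
            mask = np.zeros(self.n_vertices, dtype=bool)
            be = self.boundary_edges
            if len(be):
                mask[be.ravel()] = True
            self._cache["boundary_mask"] = mask
        return self._cache["boundary_mask"]

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), validate=False)

    def __repr__(self) -> str:  # pragma: no cover
        return f"TriangleMesh(n_vertices={self.n_vertices}, n_faces={self.n_faces})"


@dataclass(frozen=True)
class IntersectionPair:
    """Unordered pair of non-adjacent faces whose triangles intersect."""

    face_a: int
    face_b: int

    def __post_init__(self):
        if self.face_a > self.face_b:
            object.__setattr__(self, "face_a", self.face_b)
            object.__setattr__(self, "face_b", self.face_a)


#: Table-style column order for CSV serialization
_REPORT_COLUMNS = [
    "n_vertices", "q_min", "q_avg", "theta_min", "theta_min_mean", "theta_max",
    "pct_below_30", "pct_regular_vertices", "ar_max", "ar_avg",
    "genus", "area", "volume", "n_self_intersecting_pairs",
]


@dataclass
class QualityReport:
    """Mesh-quality statistics bundle.

    Angles in degrees, area in A^2, volume in A^3.  ``ar_max``/``ar_avg``
    carry the undefined sentinel (inf) when any triangle is degenerate;
    ``genus`` and ``volume`` are None for open meshes.
    """

    n_vertices: int
    q_min: float
    q_avg: float
    theta_min: float
    theta_min_mean: float
    theta_max: float
    pct_below_30: float
    pct_regular_vertices: float
    ar_max: float
    ar_avg: float
    genus: int | None
    area: float
    volume: float | None
    n_self_intersecting_pairs: int | None = None

    @staticmethod
    def _fmt(v):
        if v is None:
            return "undef."
        if isinstance(v, float) and math.isinf(v):
            return "undef."
        return v

    def to_dict(self) -> dict:
        return {f.name: self._fmt(getattr(self, f.name)) for f in dc_fields(self)}

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def to_csv(self) -> str:
        header = ",".join(_REPORT_COLUMNS)
        row = ",".join(str(self._fmt(getattr(self, c))) for c in _REPORT_COLUMNS)
        return header + "\n" + row + "\n"


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None and fmt != "auto":
        return fmt.lower()
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("off", "ply", "obj"):
        return suffix
    raise MeshFormatError(f"cannot infer mesh format from '{path.name}'")


def _read_off(path: Path) -> tuple[np.ndarray, np.ndarray]:
    lines = path.read_text().splitlines()
    tokens: list[tuple[int, list[str]]] = []
    for ln, raw in enumerate(lines, start=1):
        s = raw.split("#", 1)[0].strip()
        if s:
            tokens.append((ln, s.split()))
    if not tokens:
        raise MeshFormatError(f"{path}: empty OFF file")
    ln, head = tokens[0]
    rest = tokens[1:]
    if head[0].upper() != "OFF":
        raise MeshFormatError(f"{path}: line {ln}: missing OFF header")
    if len(head) > 1:
        counts = head[1:4]
    else:
        if not rest:
            raise MeshFormatError(f"{path}: missing count line")
        ln, counts = rest[0][0], rest[0][1]
        rest = rest[1:]
    try:
        nv, nf = int(counts[0]), int(counts[1])
    except (ValueError, IndexError):
        raise MeshFormatError(f"{path}: line {ln}: bad count line") from None
    if len(rest) < nv + nf:
        raise MeshFormatError(f"{path}: truncated OFF body")
    verts = np.empty((nv, 3))
    for i in range(nv):
        ln, t = rest[i]
        try:
            verts[i] = [float(t[0]), float(t[1]), float(t[2])]
        except (ValueError, IndexError):
            raise MeshFormatError(f"{path}: line {ln}: bad vertex record") from None
    faces = np.empty((nf, 3), dtype=np.int64)
    for i in range(nf):
        ln, t = rest[nv + i]
        try:
            cnt = int(t[0])
        except (ValueError, IndexError):
            raise MeshFormatError(f"{path}: line {ln}: bad face record") from None
        if cnt != 3:
            raise UnsupportedElementError(
                f"{path}: line {ln}: {cnt}-gon face; only triangles are supported"
            )
        try:
            faces[i] = [int(t[1]), int(t[2]), int(t[3])]
        except (ValueError, IndexError):
            raise MeshFormatError(f"{path}: line {ln}: bad face record") from None
    return verts, faces


def _read_obj(path: Path) -> tuple[np.ndarray, np.ndarray]:
    verts: list[list[float]] = []
    faces: list[list[int]] = []
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        s = raw.strip()
        if not s or s.startswith("#"):
            continue
        t = s.split()
        if t[0] == "v":
            try:
                verts.append([float(t[1]), float(t[2]), float(t[3])])
            except (ValueError, IndexError):
                raise MeshFormatError(f"{path}: line {ln}: bad vertex record") from None
        elif t[0] == "f":
            refs = t[1:]
            if len(refs) != 3:
                raise UnsupportedElementError(
                    f"{path}: line {ln}: {len(refs)}-gon face; only triangles are supported"
                )
            idx = []
            for r in refs:
                try:
                    i = int(r.split("/", 1)[0])
                except ValueError:
                    raise MeshFormatError(
                        f"{path}: line {ln}: bad face reference '{r}'"
                    ) from None
                idx.append(i - 1 if i > 0 else len(verts) + i)
            faces.append(idx)
        # other record types (vn, vt, o, g, s, usemtl ...) are ignored
    if not verts:
        raise MeshFormatError(f"{path}: no vertices found")
    return np.asarray(verts, dtype=float), np.asarray(faces, dtype=np.int64).reshape(-1, 3)


def _read_ply(path: Path) -> tuple[np.ndarray, np.ndarray]:
    import trimesh

    try:
        tm = trimesh.load(str(path), file_type="ply", process=False)
    except Exception as exc:
        raise MeshFormatError(f"{path}: PLY parse failure: {exc}") from exc
    if not hasattr(tm, "faces") or len(tm.faces) == 0:
        raise MeshFormatError(f"{path}: PLY file has no triangle faces")
    f = np.asarray(tm.faces)
    if f.shape[1] != 3:
        raise UnsupportedElementError(f"{path}: non-triangle faces in PLY")
    return np.asarray(tm.vertices, dtype=float), f.astype(np.int64)


def read_mesh(path, format: str | None = "auto") -> TriangleMesh:
    """Read an OFF, PLY, or OBJ triangle mesh.

    Duplicate-coordinate vertices are kept as-is; raw molecular meshes
    retain their redundancy.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format)
    if fmt == "off":
        v, f = _read_off(path)
    elif fmt == "obj":
        v, f = _read_obj(path)
    elif fmt == "ply":
        v, f = _read_ply(path)
    else:
        raise MeshFormatError(f"unsupported format '{fmt}'")
    return TriangleMesh(v, f)


def write_mesh(mesh: TriangleMesh, path, format: str | None = "auto") -> None:
    """Write a mesh as OFF, PLY (binary little-endian), or OBJ (1-based)."""
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "off":
        lines = ["OFF", f"{mesh.n_vertices} {mesh.n_faces} 0"]
        lines += [f"{x:.17g} {y:.17g} {z:.17g}" for x, y, z in mesh.vertices]
        lines += [f"3 {a} {b} {c}" for a, b, c in mesh.faces]
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "obj":
        lines = [f"v {x:.17g} {y:.17g} {z:.17g}" for x, y, z in mesh.vertices]
        lines += [f"f {a + 1} {b + 1} {c + 1}" for a, b, c in mesh.faces]
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "ply":
        import trimesh

        tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
        tm.export(str(path), file_type="ply")
    else:
        raise MeshFormatError(f"unsupported format '{fmt}'")


# ---------------------------------------------------------------------------
# per-element metrics
# ---------------------------------------------------------------------------

def triangle_angles(mesh: TriangleMesh, face: int) -> tuple[float, float, float]:
    """Interior angles (degrees) of one face; they sum to 180 within 1e-6."""
    p0, p1, p2 = mesh.vertices[mesh.faces[face]]
    try:
        return geom.angles_deg(tuple(p0), tuple(p1), tuple(p2))
    except ValueError:
        raise DegenerateFaceError(face) from None


def triangle_quality(mesh: TriangleMesh, face: int) -> float:
    p0, p1, p2 = mesh.vertices[mesh.faces[face]]
    return geom.quality_scalar(tuple(p0), tuple(p1), tuple(p2))


def triangle_aspect_ratio(mesh: TriangleMesh, face: int) -> float:
    p0, p1, p2 = mesh.vertices[mesh.faces[face]]
    return geom.aspect_ratio_scalar(tuple(p0), tuple(p1), tuple(p2))


def vertex_aspect_ratio(mesh: TriangleMesh, vertex: int) -> float:
    """Mean aspect ratio of the faces incident to a vertex.

    Any incident degenerate triangle makes the result the undefined
    sentinel, which compares worse than every finite value.
    """
    fids = mesh.vertex_faces[vertex]
    if not fids:
        raise IsolatedVertexError(f"vertex {vertex} has no incident faces")
    total = 0.0
    for fi in fids:
        ar = triangle_aspect_ratio(mesh, fi)
        if math.isinf(ar):
            return UNDEFINED
        total += ar
    return total / len(fids)


def euler_number(mesh: TriangleMesh) -> int:
    return mesh.n_vertices + mesh.n_faces - mesh.n_edges


def genus(mesh: TriangleMesh) -> int:
    """genus = 1 - E/2 for a closed surface; may be negative (cavities)."""
    if not mesh.is_closed:
        raise NotClosedError("genus requires a closed mesh (every edge on 2 faces)")
    return 1 - euler_number(mesh) // 2


def surface_area(mesh: TriangleMesh) -> float:
    return float(geom.face_areas(mesh.vertices, mesh.faces).sum())


def enclosed_volume(mesh: TriangleMesh) -> float:
    """|sum of signed tetrahedron volumes| via the divergence theorem."""
    if not mesh.is_closed:
        raise NotClosedError("volume requires a closed mesh")
    P = mesh.vertices[mesh.faces]
    signed = np.einsum("ij,ij->i", P[:, 0], np.cross(P[:, 1], P[:, 2])) / 6.0
    return float(abs(signed.sum()))


def regular_vertex_ratio(mesh: TriangleMesh) -> float:
    """Percent of vertices with valence 5-7 (interior) or 3-5 (boundary)."""
    if mesh.n_vertices == 0:
        return 0.0
    val = mesh.vertex_valence
    boundary = mesh.boundary_vertex_mask
    regular = np.where(
        boundary, (val >= 3) & (val <= 5), (val >= 5) & (val <= 7)
    )
    return 100.0 * float(regular.sum()) / mesh.n_vertices


# ---------------------------------------------------------------------------
# self-intersections
# ---------------------------------------------------------------------------

def _share_vertex(f1, f2) -> bool:
    return bool(set(f1) & set(f2))


def _exact_pairs(mesh: TriangleMesh, candidates) -> list[IntersectionPair]:
    V, F = mesh.vertices, mesh.faces
    out = []
    for i, j in candidates:
        if _share_vertex(F[i], F[j]):
            continue
        if geom.tri_tri_intersect(V[F[i]], V[F[j]]):
            out.append(IntersectionPair(int(i), int(j)))
    return sorted(out, key=lambda p: (p.face_a, p.face_b))


def self_intersections(mesh: TriangleMesh) -> list[IntersectionPair]:
    """All unordered pairs of non-adjacent faces whose triangles intersect.

    Broad phase: a uniform spatial hash over face AABBs; narrow phase:
    the exact triangle-triangle test.  Pairs sharing a vertex index are
    never reported.
    """
    m = mesh.n_faces
    if m < 2:
        return []
    P = mesh.vertices[mesh.faces]
    lo = P.min(axis=1)
    hi = P.max(axis=1)
    extent = hi - lo
    cell = float(np.median(extent.max(axis=1))) * 2.0
    if cell <= 0:
        cell = float(extent.max()) or 1.0

    grid: dict[tuple[int, int, int], list[int]] = {}
    ilo = np.floor(lo / cell).astype(np.int64)
    ihi = np.floor(hi / cell).astype(np.int64)
    for fi in range(m):
        x0, y0, z0 = ilo[fi]
        x1, y1, z1 = ihi[fi]
        for x in range(x0, x1 + 1):
            for y in range(y0, y1 + 1):
                for z in range(z0, z1 + 1):
                    grid.setdefault((x, y, z), []).append(fi)

    candidates = set()
    for bucket in grid.values():
        n = len(bucket)
        if n < 2:
            continue
        for a in range(n):
            i = bucket[a]
            for b in range(a + 1, n):
                j = bucket[b]
                pair = (i, j) if i < j else (j, i)
                if pair in candidates:
                    continue
                if (lo[pair[0]] <= hi[pair[1]]).all() and (lo[pair[1]] <= hi[pair[0]]).all():
                    candidates.add(pair)
    return _exact_pairs(mesh, candidates)


def self_intersections_brute_force(mesh: TriangleMesh) -> list[IntersectionPair]:
    """O(n^2) all-pairs oracle (AABB prefilter, then the exact test).

    Independent of the spatial-hash broad phase; intended for validation
    on desk-scale meshes.
    """
    m = mesh.n_faces
    if m < 2:
        return []
    P = mesh.vertices[mesh.faces]
    lo = P.min(axis=1)
    hi = P.max(axis=1)
    overlap = np.ones((m, m), dtype=bool)
    for ax in range(3):
        overlap &= lo[:, ax][:, None] <= hi[:, ax][None, :]
        overlap &= lo[:, ax][None, :] <= hi[:, ax][:, None]
    iu = np.triu_indices(m, k=1)
    keep = overlap[iu]
    candidates = list(zip(iu[0][keep].tolist(), iu[1][keep].tolist()))
    return _exact_pairs(mesh, candidates)


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

def quality_report(mesh: TriangleMesh, count_intersections: bool = True) -> QualityReport:
    """Compute the full quality-statistics bundle for a mesh.

    ``pct_below_30`` counts faces whose minimum angle is < 30 deg as a
    percentage of all faces.  On open meshes, genus and volume are left
    undefined instead of raising.
    """
    V, F = mesh.vertices, mesh.faces
    q = geom.face_qualities(V, F)
    ang = geom.face_angles_deg(V, F)
    amin = ang.min(axis=1)
    amax = ang.max(axis=1)
    ar = geom.face_aspect_ratios(V, F)
    finite = np.isfinite(ar)
    if finite.all() and len(ar):
        ar_max, ar_avg = float(ar.max()), float(ar.mean())
    else:
        ar_max = ar_avg = UNDEFINED

    try:
        g: int | None = genus(mesh)
    except NotClosedError:
        g = None
    try:
        vol: float | None = enclosed_volume(mesh)
    except NotClosedError:
        vol = None

    n_int: int | None = None
    if count_intersections:
        n_int = len(self_intersections(mesh))

    return QualityReport(
        n_vertices=mesh.n_vertices,
        q_min=float(q.min()) if len(q) else 0.0,
        q_avg=float(q.mean()) if len(q) else 0.0,
        theta_min=float(amin.min()) if len(ang) else 0.0,
        theta_min_mean=float(amin.mean()) if len(ang) else 0.0,
        theta_max=float(amax.max()) if len(ang) else 0.0,
        pct_below_30=100.0 * float((amin < 30.0).sum()) / len(F) if len(F) else 0.0,
        pct_regular_vertices=regular_vertex_ratio(mesh),
        ar_max=ar_max,
        ar_avg=ar_avg,
        genus=g,
        area=surface_area(mesh) if len(F) else 0.0,
        volume=vol,
        n_self_intersecting_pairs=n_int,
    )
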