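"""Synthetic raw molecular surface meshes for testing and benchmarking.

Real molecular surfacers emit triangulations of the Gaussian molecular
surface — the level set {phi(x) = c} of a sum of per-atom Gaussian
kernels

    phi(x) = sum_i exp(-d * (||x - x_i||^2 - r_i^2))

with decay rate d and isovalue c — and those raw meshes arrive with
near-zero-degree angles, redundant (over-dense) vertices, and narrow
bridges of tiny triangles.  This module reproduces both halves: a
marching-cubes extraction of the Gaussian surface from a toy atom set,
and a deterministic defect injector that emulates the raw-mesh pathology
while keeping the mesh closed and edge-manifold.

Defaults (5-atom tetrahedral cluster, d = 0.5, c = 1.0, 4 voxels/A)
yield a desk-scale surface of roughly 5-20k faces.  They are this
package's choices for emulating raw-surfacer statistics, not constants
of any external tool.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import EmptySurfaceError, PQRParseError, RecipeError
from .mesh_core import TriangleMesh
from ._edit import EditableMesh

__all__ = [
    "AtomSet",
    "GaussianSurfaceSpec",
    "DefectRecipe",
    "read_pqr",
    "write_pqr",
    "gaussian_field",
    "extract_gaussian_surface",
    "inject_degeneracies",
    "make_icosphere",
    "make_torus",
    "default_atom_set",
    "default_raw_fixture",
]


@dataclass
class AtomSet:
    """Atom centers (A), radii (A), and charges (e) from a PQR-style source."""

    centers: np.ndarray
    radii: np.ndarray
    charges: np.ndarray

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        self.charges = np.atleast_1d(np.asarray(self.charges, dtype=float))
        if len(self.centers) < 1:
            raise ValueError("AtomSet needs at least one atom")
        if (self.radii <= 0).any():
            raise ValueError("all radii must be positive")

    @property
    def n(self) -> int:
        return len(self.centers)


@dataclass
class GaussianSurfaceSpec:
    """Isovalue c, decay d, and sampling grid for the Gaussian surface.

    ``resolution`` is in voxels per Angstrom; ``padding`` extends the grid
    beyond the atom bounding box (default max(2/sqrt(d), 2 A), bounding
    the truncation error of the exp(-d * dist^2) tail).
    """

    isovalue: float = 1.0
    decay: float = 0.5
    resolution: float = 4.0
    padding: float | None = None

    def __post_init__(self):
        if self.isovalue <= 0 or self.decay <= 0 or self.resolution <= 0:
            raise ValueError("isovalue, decay, and resolution must be positive")
        if self.padding is None:
            self.padding = max(2.0 / np.sqrt(self.decay), 2.0)
        if self.padding <= 0:
            raise ValueError("padding must be positive")


@dataclass
class DefectRecipe:
    """Deterministic defect injection parameters.

    ``sliver_fraction`` of faces receive a near-endpoint edge split that
    creates sub-degree angles; ``redundant_fraction`` of faces receive a
    1-to-3 barycentric split (a redundant valence-3 vertex);
    ``narrow_bridges`` thin tubes of tiny triangles are welded between
    distant patches of the surface.
    """

    sliver_fraction: float = 0.0
    redundant_fraction: float = 0.0
    narrow_bridges: int = 0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.sliver_fraction <= 1.0):
            raise ValueError("sliver_fraction must be in [0, 1]")
        if not (0.0 <= self.redundant_fraction <= 1.0):
            raise ValueError("redundant_fraction must be in [0, 1]")
        if self.narrow_bridges < 0:
            raise ValueError("narrow_bridges must be >= 0")


# ---------------------------------------------------------------------------
# PQR
# ---------------------------------------------------------------------------

def read_pqr(path) -> AtomSet:
    """Parse a PQR file: ATOM/HETATM records with x y z charge radius as
    the last five whitespace-separated numeric fields.

    The whitespace dialect tolerates extra tokens (chain identifiers,
    insertion codes); fixed-column parsing is deliberately avoided.
    """
    centers, radii, charges = [], [], []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        rec = raw.split()
        if not rec or rec[0] not in ("ATOM", "HETATM"):
            continue
        try:
            nums = [float(t) for t in rec[-5:]]
        except (ValueError, IndexError):
            raise PQRParseError(ln, "expected x y z charge radius as last five fields")
        if len(rec) < 6:
            raise PQRParseError(ln, "record too short")
        x, y, z, q, r = nums
        if r <= 0:
            raise PQRParseError(ln, f"non-positive radius {r}")
        centers.append([x, y, z])
        charges.append(q)
        radii.append(r)
    if not centers:
        raise PQRParseError(0, "no ATOM/HETATM records found")
    return AtomSet(np.array(centers), np.array(radii), np.array(charges))


def write_pqr(atoms: AtomSet, path) -> None:
    """Write a minimal whitespace-delimited PQR file (1e-3 A precision)."""
    lines = []
    for i in range(atoms.n):
        x, y, z = atoms.centers[i]
        lines.append(
            f"ATOM {i + 1} X RES 1 {x:.3f} {y:.3f} {z:.3f} "
            f"{atoms.charges[i]:.4f} {atoms.radii[i]:.4f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Gaussian surface
# ---------------------------------------------------------------------------

def gaussian_field(atoms: AtomSet, decay: float, points) -> np.ndarray:
    """phi(p) = sum_i exp(-d (||p - x_i||^2 - r_i^2)); strictly positive."""
    if decay <= 0:
        raise ValueError("decay must be positive")
    p = np.atleast_2d(np.asarray(points, dtype=float))
    d2 = ((p[:, None, :] - atoms.centers[None, :, :]) ** 2).sum(axis=2)
    phi = np.exp(-decay * (d2 - atoms.radii[None, :] ** 2)).sum(axis=1)
    return phi if np.asarray(points).ndim > 1 else float(phi[0])


def extract_gaussian_surface(atoms: AtomSet, spec: GaussianSurfaceSpec) -> TriangleMesh:
    """Marching-cubes triangulation of the level set {phi = c}.

    The grid covers all atoms plus ``spec.padding``; output is a closed,
    outward-oriented triangle mesh.
    """
    from skimage import measure
    import trimesh

    pad = float(spec.padding)
    lo = atoms.centers.min(axis=0) - atoms.radii.max() - pad
    hi = atoms.centers.max(axis=0) + atoms.radii.max() + pad
    h = 1.0 / spec.resolution
    ns = np.maximum(np.ceil((hi - lo) / h).astype(int) + 1, 2)
    axes = [lo[k] + h * np.arange(ns[k]) for k in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    # chunked evaluation keeps the (n_points, n_atoms) buffer small
    phi = np.empty(len(pts))
    step = 200_000
    for s in range(0, len(pts), step):
        phi[s : s + step] = gaussian_field(atoms, spec.decay, pts[s : s + step])
    vol = phi.reshape(ns)
    if vol.max() <= spec.isovalue:
        raise EmptySurfaceError(
            f"isovalue {spec.isovalue} above the field maximum {vol.max():.4g}"
        )
    verts, faces, _, _ = measure.marching_cubes(
        vol, level=spec.isovalue, spacing=(h, h, h), allow_degenerate=False
    )
    verts = verts + lo
    # weld the duplicate vertices marching cubes emits on cell borders and
    # orient outward; trimesh's processing handles both
    tm = trimesh.Trimesh(verts, faces, process=True, validate=True)
    tm.fix_normals()
    if tm.volume < 0:
        tm.invert()
    mesh = TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
    if not mesh.is_closed:
        raise EmptySurfaceError("marching-cubes output is not closed; refine the grid")
    return mesh


# ---------------------------------------------------------------------------
# reference shapes
# ---------------------------------------------------------------------------

def make_icosphere(subdivisions: int = 2, radius: float = 1.0) -> TriangleMesh:
    import trimesh

    if radius <= 0:
        raise ValueError("radius must be positive")
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def make_torus(major_radius: float = 2.0, minor_radius: float = 0.5,
               major_sections: int = 24, minor_sections: int = 12) -> TriangleMesh:
    import trimesh

    if major_radius <= 0 or minor_radius <= 0:
        raise ValueError("radii must be positive")
    tm = trimesh.creation.torus(
        major_radius=major_radius, minor_radius=minor_radius,
        major_sections=major_sections, minor_sections=minor_sections,
    )
    tm.fix_normals()
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


# ---------------------------------------------------------------------------
# defect injection
# ---------------------------------------------------------------------------

def _shrink_face_to_tiny_hole(em: EditableMesh, fid: int, scale: float = 0.01):
    """Replace a face by a ring of 6 thin triangles around a tiny central
    triangle, then remove the central triangle.

    Returns the 3 new (tiny-loop) vertex ids.  The ring triangles are long
    and thin — exactly the 'narrow region of small triangles' pathology.
    """
    a, b, c = em.F[fid]
    pa, pb, pc = em.V[a], em.V[b], em.V[c]
    centroid = (pa + pb + pc) / 3.0
    em.remove_face(fid)
    small = [em.add_vertex(centroid + scale * (p - centroid)) for p in (pa, pb, pc)]
    sa, sb, sc = small
    # ring of 6 triangles between outer loop (a,b,c) and inner loop (sa,sb,sc)
    for (u, v, su, sv) in ((a, b, sa, sb), (b, c, sb, sc), (c, a, sc, sa)):
        em.add_face(u, v, sv)
        em.add_face(u, sv, su)
    return small


def _add_narrow_bridge(em: EditableMesh, rng: np.random.Generator) -> None:
    """Weld a thin tube of tiny triangles between two distant faces."""
    fids = sorted(em.F)
    if len(fids) < 50:
        raise RecipeError("mesh too small for a narrow bridge")
    f1 = fids[int(rng.integers(len(fids)))]
    c1 = np.mean(em.face_points(f1), axis=0)
    # farthest face from f1 with no shared vertices
    best, best_d = None, -1.0
    sample = rng.choice(fids, size=min(200, len(fids)), replace=False)
    v1 = set(em.F[f1])
    for f2 in sample:
        if f2 == f1 or set(em.F[f2]) & v1:
            continue
        d = float(np.linalg.norm(np.mean(em.face_points(f2), axis=0) - c1))
        if d > best_d:
            best, best_d = int(f2), d
    if best is None:
        raise RecipeError("no eligible partner face for a bridge")
    loop1 = _shrink_face_to_tiny_hole(em, f1)
    loop2 = _shrink_face_to_tiny_hole(em, best)
    # connect the two tiny triangular holes with a 6-triangle tube; the
    # second loop runs reversed so both holes are traversed forward by the
    # tube faces (consistent outward orientation)
    l2 = list(reversed(loop2))
    for i in range(3):
        u, un = loop1[i], loop1[(i + 1) % 3]
        w, wn = l2[i], l2[(i + 1) % 3]
        em.add_face(u, un, wn)
        em.add_face(u, wn, w)


def inject_degeneracies(mesh: TriangleMesh, recipe: DefectRecipe) -> TriangleMesh:
    """Inject slivers, redundant vertices, and narrow bridges.

    Output stays closed and edge-manifold; identical recipes (same seed)
    give bit-identical outputs.  An all-zero recipe returns the input
    unchanged.
    """
    if (recipe.sliver_fraction == 0.0 and recipe.redundant_fraction == 0.0
            and recipe.narrow_bridges == 0):
        return mesh
    if not mesh.is_closed:
        raise RecipeError("defect injection requires a closed manifold mesh")
    rng = np.random.default_rng(recipe.seed)
    em = EditableMesh.from_mesh(mesh)
    m = mesh.n_faces

    n_sliver = int(round(recipe.sliver_fraction * m))
    n_redund = int(round(recipe.redundant_fraction * m))
    order = rng.permutation(m)
    sliver_faces = order[:n_sliver]
    redundant_faces = order[n_sliver : n_sliver + n_redund]
    if n_sliver + n_redund > m:
        raise RecipeError("sliver + redundant fractions exceed the face count")

    # slivers: split one edge of the face very close to an endpoint; the
    # two child triangles on each side have a sub-degree angle at the split
    for fi in sliver_faces:
        if fi not in em.F:
            continue
        a, b, c = em.F[fi]
        pa, pb = em.V[a], em.V[b]
        t = 1e-4 * (0.5 + rng.random())
        em.split_edge(a, b, pa + t * (pb - pa))

    # redundant vertices: 1-to-3 barycentric face split (valence-3 vertex)
    for fi in redundant_faces:
        if fi not in em.F:
            continue
        a, b, c = em.F[fi]
        bary = (em.V[a] + em.V[b] + em.V[c]) / 3.0
        em.remove_face(fi)
        w = em.add_vertex(bary)
        em.add_face(a, b, w)
        em.add_face(b, c, w)
        em.add_face(c, a, w)

    for _ in range(recipe.narrow_bridges):
        _add_narrow_bridge(em, rng)

    out, _, _ = em.to_mesh()
    out._validate()
    return out


# ---------------------------------------------------------------------------
# default fixtures
# ---------------------------------------------------------------------------

def default_atom_set() -> AtomSet:
    """Five-atom toy cluster: a tetrahedron of radius-1.5..2.0 atoms plus a
    center atom, spaced so the Gaussian surface fuses into one component."""
    s = 2.2
    centers = np.array([
        [s, s, s],
        [s, -s, -s],
        [-s, s, -s],
        [-s, -s, s],
        [0.0, 0.0, 0.0],
    ])
    radii = np.array([1.5, 1.6, 1.8, 2.0, 1.7])
    charges = np.array([-0.5, 0.25, 0.25, -0.5, 0.5])
    return AtomSet(centers, radii, charges)


def default_raw_fixture(resolution: float = 4.0,
                        sliver_fraction: float = 0.05,
                        redundant_fraction: float = 0.05,
                        narrow_bridges: int = 1,
                        seed: int = 42) -> TriangleMesh:
    """The standard degraded fixture: 5-atom Gaussian surface (d = 0.5,
    c = 1.0) plus injected slivers, redundant vertices, and one narrow
    bridge.  ``resolution`` scales the face count (4 voxels/A gives the
    desk-scale ~5-20k-face mesh; ~1.5 gives a <2k-face variant)."""
    atoms = default_atom_set()
    spec = GaussianSurfaceSpec(isovalue=1.0, decay=0.5, resolution=resolution)
    surf = extract_gaussian_surface(atoms, spec)
    recipe = DefectRecipe(
        sliver_fraction=sliver_fraction,
        redundant_fraction=redundant_fraction,
        narrow_bridges=narrow_bridges,
        seed=seed,
    )
    return inject_degeneracies(surf, recipe)
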