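"""Invalid-region labeling, excision, and hole filling."""
import math

import numpy as np
import pytest

import molremesh as mr
from molremesh import fixture_gen as fg
from molremesh.cut_fill import (
    HoleBoundary,
    cut_and_fill,
    cut_regions,
    detect_narrow_regions,
    fill_hole,
    invalid_regions,
    label_small_triangles,
)
from molremesh.errors import InvalidHoleError

from conftest import planar_grid


def inject_sliver(mesh, face=0, t=1e-3):
    """Split one edge of a face near its endpoint; returns the new mesh."""
    from molremesh._edit import EditableMesh

    em = EditableMesh.from_mesh(mesh)
    a, b, _ = em.F[face]
    em.split_edge(a, b, em.V[a] + t * (em.V[b] - em.V[a]))
    out, _, _ = em.to_mesh()
    return out


class TestLabeling:
    def test_clean_mesh_empty(self, icosahedron):
        assert label_small_triangles(icosahedron, 30.0) == set()

    def test_threshold_is_strict(self, icosahedron):
        # all angles exactly 60: not labeled even at theta_min = 59.999...60
        assert label_small_triangles(icosahedron, 59.9999) == set()

    def test_matches_full_scan_oracle(self, raw_fixture_small):
        got = label_small_triangles(raw_fixture_small, 15.0)
        expected = set()
        for fi in range(raw_fixture_small.n_faces):
            try:
                angs = mr.triangle_angles(raw_fixture_small, fi)
            except mr.errors.DegenerateFaceError:
                expected.add(fi)
                continue
            if min(angs) < 15.0:
                expected.add(fi)
        assert got == expected

    def test_threshold_range_validated(self, icosahedron):
        with pytest.raises(ValueError):
            label_small_triangles(icosahedron, 0.0)
        with pytest.raises(ValueError):
            label_small_triangles(icosahedron, 60.0)


class TestInvalidRegions:
    def test_no_small_triangles_empty(self, icosahedron):
        assert invalid_regions(icosahedron, 30.0) == []

    def test_isolated_sliver_region_is_one_ring_union(self):
        grid = planar_grid(5)
        bad = inject_sliver(grid, face=12)
        regions = invalid_regions(bad, 15.0)
        assert len(regions) == 1
        small = label_small_triangles(bad, 15.0)
        expected = set()
        vfaces = bad.vertex_faces
        for fi in small:
            for v in bad.faces[fi]:
                expected.update(vfaces[int(v)])
        assert regions[0].faces == expected
        assert small <= regions[0].faces

    def test_adjacent_slivers_merge(self):
        grid = planar_grid(5)
        bad = inject_sliver(inject_sliver(grid, face=12), face=13)
        regions = invalid_regions(bad, 15.0)
        assert len(regions) == 1


class TestNarrowRegions:
    def test_clean_mesh_empty(self, icosphere3):
        assert detect_narrow_regions(icosphere3, 30.0) == []

    def test_isolated_sliver_not_narrow(self):
        bad = inject_sliver(planar_grid(5), face=12)
        assert detect_narrow_regions(bad, 15.0) == []

    def test_bridge_fixture_found(self, raw_fixture_small, clean_surface):
        narrow = detect_narrow_regions(raw_fixture_small, 15.0)
        assert len(narrow) >= 1
        # removing the largest narrow component must open >= 2 loops
        biggest = max(narrow, key=lambda r: len(r.faces))
        cut, holes = cut_regions(raw_fixture_small, [biggest])
        assert len(holes) >= 2


class TestCutRegions:
    def test_single_face_removal_gives_3_loop(self, icosphere3):
        region = mr.RegionSelection(faces={0},
                                    vertices=set(map(int, icosphere3.faces[0])))
        cut, holes = cut_regions(icosphere3, [region])
        assert cut.n_faces == icosphere3.n_faces - 1
        assert len(holes) == 1
        assert len(holes[0].loop) == 3

    def test_hole_orientation_fillable(self, icosphere3):
        region = mr.RegionSelection(faces={5},
                                    vertices=set(map(int, icosphere3.faces[5])))
        cut, holes = cut_regions(icosphere3, [region])
        filled, patch = fill_hole(cut, holes[0])
        assert filled.is_closed
        assert mr.genus(filled) == 0

    def test_vertex_bookkeeping(self, icosphere3):
        # cut a one-ring: its center vertex is orphaned and removed
        v = 7
        fids = set(icosphere3.vertex_faces[v])
        verts = {int(x) for fi in fids for x in icosphere3.faces[fi]}
        cut, holes = cut_regions(
            icosphere3, [mr.RegionSelection(faces=fids, vertices=verts)])
        assert cut.n_vertices == icosphere3.n_vertices - 1
        assert len(holes) == 1


class TestFillHole:
    def test_three_vertex_hole_single_triangle(self, icosphere3):
        region = mr.RegionSelection(faces={0},
                                    vertices=set(map(int, icosphere3.faces[0])))
        cut, holes = cut_regions(icosphere3, [region])
        filled, patch = fill_hole(cut, holes[0])
        assert filled.n_faces == icosphere3.n_faces
        assert filled.is_closed
        assert len(patch.faces) == 1

    def test_regular_hexagonal_hole_no_interior_vertex(self):
        # closed hexagonal drum with the top cap missing: convex 6-loop
        k = 6
        top = [[math.cos(2 * math.pi * i / k), math.sin(2 * math.pi * i / k), 1.0]
               for i in range(k)]
        bot = [[math.cos(2 * math.pi * i / k), math.sin(2 * math.pi * i / k), -1.0]
               for i in range(k)]
        V = np.array(top + bot + [[0, 0, -1.5]])
        F = []
        for i in range(k):
            a, b = i, (i + 1) % k
            F.append([a, k + a, b])
            F.append([b, k + a, k + b])
        for i in range(k):
            F.append([k + (i + 1) % k, k + i, 2 * k])
        open_mesh = mr.TriangleMesh(V, np.array(F))
        e_bar = 2.0  # generous: no post-split of new edges
        hole = HoleBoundary(loop=list(range(k)), mean_edge_length=e_bar)
        filled, patch = fill_hole(open_mesh, hole)
        assert filled.is_closed
        for fi in patch.faces:
            assert min(mr.triangle_angles(filled, fi)) >= 15.0
        assert len(patch.vertices - set(range(filled.n_vertices))) == 0

    def test_stalled_front_inserts_interior_vertex(self):
        # long thin rectangular chimney: every ear on the 8-loop is < 15 deg
        w, l = 0.1, 4.0
        loop2d = [(0, 0), (l / 3, 0), (2 * l / 3, 0), (l, 0),
                  (l, w), (2 * l / 3, w), (l / 3, w), (0, w)]
        n = len(loop2d)
        top = [[x, y, 0.5] for x, y in loop2d]
        bot = [[x, y, -0.5] for x, y in loop2d]
        V = np.array(top + bot + [[l / 2, w / 2, -1.0]])
        F = []
        for i in range(n):
            a, b = i, (i + 1) % n
            F.append([a, n + a, b])
            F.append([b, n + a, n + b])
        for i in range(n):
            F.append([n + (i + 1) % n, n + i, 2 * n])
        open_mesh = mr.TriangleMesh(V, np.array(F))
        hole = HoleBoundary(loop=list(range(n)), mean_edge_length=10.0)
        filled, patch = fill_hole(open_mesh, hole)
        assert filled.is_closed
        assert len(patch.vertices) >= 1  # interior vertex was inserted

    def test_too_short_loop_rejected(self):
        with pytest.raises(InvalidHoleError):
            HoleBoundary(loop=[0, 1], mean_edge_length=1.0)

    def test_long_new_edges_split_by_07_rule(self, icosphere3):
        v = 3
        fids = set(icosphere3.vertex_faces[v])
        verts = {int(x) for fi in fids for x in icosphere3.faces[fi]}
        cut, holes = cut_regions(
            icosphere3, [mr.RegionSelection(faces=fids, vertices=verts)])
        hole = holes[0]
        filled, patch = fill_hole(cut, hole)
        # the one-ring hole is a 5-loop whose ear chords exceed 0.7 e_bar,
        # so the split rule must have inserted midpoint vertices; and no
        # surviving chord between two loop vertices may exceed the bound
        assert len(patch.vertices - set(hole.loop)) >= 1
        loop = set(hole.loop)
        thr = 0.7 * hole.mean_edge_length
        for fi in sorted(patch.faces):
            a, b, c = filled.faces[fi]
            for u, w in ((a, b), (b, c), (c, a)):
                if int(u) in loop and int(w) in loop:
                    e = tuple(sorted((int(u), int(w))))
                    L = hole.loop
                    is_loop_edge = any(
                        e == tuple(sorted((L[i], L[(i + 1) % len(L)])))
                        for i in range(len(L)))
                    if not is_loop_edge:
                        length = np.linalg.norm(
                            filled.vertices[u] - filled.vertices[w])
                        assert length <= thr + 1e-9


class TestCutAndFill:
    def test_clean_mesh_identity(self, icosphere3):
        out, patches = cut_and_fill(icosphere3, 30.0)
        assert out is icosphere3
        assert patches == []

    def test_fixture_round1_restores_closure(self, raw_fixture_small):
        out, patches = cut_and_fill(raw_fixture_small, 15.0,
                                    reference=raw_fixture_small)
        assert out.is_closed
        assert out.is_edge_manifold
        assert len(patches) >= 1

    def test_determinism(self, raw_fixture_small):
        a, _ = cut_and_fill(raw_fixture_small, 15.0, reference=raw_fixture_small)
        b, _ = cut_and_fill(raw_fixture_small, 15.0, reference=raw_fixture_small)
        assert np.array_equal(a.vertices, b.vertices)
        assert np.array_equal(a.faces, b.faces)
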