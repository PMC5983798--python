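"""Mesh container, I/O, and quality metrics."""
import math

import numpy as np
import pytest

import molremesh as mr
from molremesh.errors import (
    IsolatedVertexError,
    MeshFormatError,
    NonManifoldError,
    NotClosedError,
    UnsupportedElementError,
)

from conftest import planar_grid


class TestTriangleMesh:
    def test_construction_validates_indices(self):
        with pytest.raises(ValueError):
            mr.TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 5]])
        with pytest.raises(ValueError):
            mr.TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 1]])

    def test_nonmanifold_edge_rejected(self):
        # three faces sharing one edge
        V = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [0, -1, 0]]
        F = [[0, 1, 2], [0, 1, 3], [1, 0, 4]]
        with pytest.raises(NonManifoldError):
            mr.TriangleMesh(V, F)

    def test_connectivity_counts(self, icosahedron):
        assert icosahedron.n_vertices == 12
        assert icosahedron.n_faces == 20
        assert icosahedron.n_edges == 30
        assert icosahedron.is_closed
        assert len(icosahedron.boundary_edges) == 0

    def test_open_mesh_boundary(self, grid_patch):
        assert not grid_patch.is_closed
        assert grid_patch.is_edge_manifold
        assert grid_patch.boundary_vertex_mask.sum() == 16  # perimeter of 5x5


class TestIO:
    def test_minimal_off(self, tmp_path):
        p = tmp_path / "t.off"
        p.write_text("OFF\n3 1 0\n0 0 0\n1 0 0\n0 1 0\n3 0 1 2\n")
        m = mr.read_mesh(p)
        assert m.n_vertices == 3 and m.n_faces == 1

    @pytest.mark.parametrize("fmt", ["off", "obj", "ply"])
    def test_round_trip(self, tmp_path, icosahedron, fmt):
        p = tmp_path / f"t.{fmt}"
        mr.write_mesh(icosahedron, p)
        m = mr.read_mesh(p)
        assert np.array_equal(m.faces, icosahedron.faces)
        if fmt == "off":  # OFF writes full precision: bit-identical
            assert np.array_equal(m.vertices, icosahedron.vertices)
        else:
            assert np.allclose(m.vertices, icosahedron.vertices)

    def test_duplicate_vertices_not_merged(self, tmp_path):
        V = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0], [0, 0, 1]]
        F = [[0, 1, 2], [3, 5, 4]]
        p = tmp_path / "dup.off"
        mr.write_mesh(mr.TriangleMesh(V, F), p)
        assert mr.read_mesh(p).n_vertices == 6

    def test_off_header_counts(self, tmp_path, icosahedron):
        p = tmp_path / "t.off"
        mr.write_mesh(icosahedron, p)
        counts = p.read_text().splitlines()[1].split()
        assert counts[:2] == ["12", "20"]

    def test_obj_one_based_indices(self, tmp_path):
        m = mr.TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
        p = tmp_path / "t.obj"
        mr.write_mesh(m, p)
        assert "f 1 2 3" in p.read_text()
        assert np.array_equal(mr.read_mesh(p).faces, [[0, 1, 2]])

    def test_parse_error_names_line(self, tmp_path):
        p = tmp_path / "bad.off"
        p.write_text("OFF\n2 1 0\n0 0 0\nnot numbers here\n3 0 1 2\n")
        with pytest.raises(MeshFormatError, match="line 4"):
            mr.read_mesh(p)

    def test_non_triangle_face_rejected(self, tmp_path):
        p = tmp_path / "quad.off"
        p.write_text("OFF\n4 1 0\n0 0 0\n1 0 0\n1 1 0\n0 1 0\n4 0 1 2 3\n")
        with pytest.raises(UnsupportedElementError):
            mr.read_mesh(p)

    def test_ply_icosphere_euler(self, tmp_path, icosahedron):
        p = tmp_path / "ico.ply"
        mr.write_mesh(icosahedron, p)
        assert mr.euler_number(mr.read_mesh(p)) == 2


class TestAngles:
    def test_equilateral(self):
        m = mr.TriangleMesh(
            [[0, 0, 0], [1, 0, 0], [0.5, math.sqrt(3) / 2, 0]], [[0, 1, 2]]
        )
        assert np.allclose(mr.triangle_angles(m, 0), (60, 60, 60))

    def test_right_isoceles(self):
        m = mr.TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
        assert np.allclose(sorted(mr.triangle_angles(m, 0)), (45, 45, 90))

    def test_sliver_matches_arccos_oracle(self):
        pts = np.array([[0, 0, 0], [4, 0, 0], [2, 0.01, 0]], dtype=float)
        m = mr.TriangleMesh(pts, [[0, 1, 2]])
        got = mr.triangle_angles(m, 0)
        # independent oracle: arccos of normalized dot products per corner
        exp = []
        for i in range(3):
            u = pts[(i + 1) % 3] - pts[i]
            v = pts[(i + 2) % 3] - pts[i]
            exp.append(math.degrees(math.acos(
                np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))))
        assert np.allclose(got, exp, atol=1e-9)
        assert abs(sum(got) - 180.0) < 1e-6

    def test_angle_sum_on_random_faces(self, raw_fixture_small):
        rng = np.random.default_rng(7)
        for fi in rng.integers(0, raw_fixture_small.n_faces, 50):
            try:
                angles = mr.triangle_angles(raw_fixture_small, int(fi))
            except mr.errors.DegenerateFaceError:
                continue
            assert abs(sum(angles) - 180.0) < 1e-6


class TestQualityAndAspectRatio:
    def test_quality_equilateral_is_one(self):
        m = mr.TriangleMesh(
            [[0, 0, 0], [1, 0, 0], [0.5, math.sqrt(3) / 2, 0]], [[0, 1, 2]]
        )
        assert mr.triangle_quality(m, 0) == pytest.approx(1.0)

    def test_quality_collinear_is_zero(self):
        m = mr.TriangleMesh([[0, 0, 0], [1, 0, 0], [2, 0, 0]], [[0, 1, 2]])
        assert mr.triangle_quality(m, 0) == 0.0

    def test_quality_right_isoceles_hand_value(self):
        m = mr.TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
        expected = (6 / math.sqrt(3)) * 0.5 / ((2 + math.sqrt(2)) / 2 * math.sqrt(2))
        assert mr.triangle_quality(m, 0) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.7174, abs=5e-5)

    def test_ar_equilateral_is_one(self):
        m = mr.TriangleMesh(
            [[0, 0, 0], [2, 0, 0], [1, math.sqrt(3), 0]], [[0, 1, 2]]
        )
        assert mr.triangle_aspect_ratio(m, 0) == pytest.approx(1.0)

    def test_ar_3_4_5_is_1_25(self):
        m = mr.TriangleMesh([[0, 0, 0], [3, 0, 0], [0, 4, 0]], [[0, 1, 2]])
        assert mr.triangle_aspect_ratio(m, 0) == pytest.approx(1.25, abs=1e-12)

    def test_ar_collinear_undefined(self):
        m = mr.TriangleMesh([[0, 0, 0], [1, 0, 0], [2, 0, 0]], [[0, 1, 2]])
        assert math.isinf(mr.triangle_aspect_ratio(m, 0))

    def test_rigid_motion_and_scale_invariance(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(3, 3))
        m = mr.TriangleMesh(pts, [[0, 1, 2]])
        q0, ar0 = mr.triangle_quality(m, 0), mr.triangle_aspect_ratio(m, 0)
        for _ in range(5):
            import scipy.spatial.transform as st

            R = st.Rotation.random(random_state=rng.integers(2**31)).as_matrix()
            s = float(rng.uniform(0.1, 10))
            m2 = mr.TriangleMesh(s * pts @ R.T + rng.normal(size=3), [[0, 1, 2]])
            assert mr.triangle_quality(m2, 0) == pytest.approx(q0, rel=1e-9)
            assert mr.triangle_aspect_ratio(m2, 0) == pytest.approx(ar0, rel=1e-9)


class TestVertexAspectRatio:
    def test_mean_of_incident(self):
        # two faces sharing edge (0,1): AR 1.25 (3-4-5) and equilateral-ish
        V = [[0, 0, 0], [3, 0, 0], [0, 4, 0], [1.5, -3 * math.sqrt(3) / 2, 0]]
        F = [[0, 1, 2], [1, 0, 3]]
        m = mr.TriangleMesh(V, F)
        ar0 = mr.triangle_aspect_ratio(m, 0)
        ar1 = mr.triangle_aspect_ratio(m, 1)
        assert mr.vertex_aspect_ratio(m, 0) == pytest.approx((ar0 + ar1) / 2)

    def test_all_equilateral_is_one(self, icosahedron):
        assert mr.vertex_aspect_ratio(icosahedron, 0) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_incident_gives_sentinel(self):
        V = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [2, 0, 0]]
        F = [[0, 1, 2], [1, 0, 3]]  # second face collinear
        m = mr.TriangleMesh(V, F)
        assert math.isinf(mr.vertex_aspect_ratio(m, 0))

    def test_isolated_vertex_raises(self):
        m = mr.TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0], [9, 9, 9]], [[0, 1, 2]])
        with pytest.raises(IsolatedVertexError):
            mr.vertex_aspect_ratio(m, 3)


class TestTopologyMetrics:
    def test_euler_icosahedron(self, icosahedron):
        assert mr.euler_number(icosahedron) == 2

    def test_euler_torus(self, torus):
        assert mr.euler_number(torus) == 0
        assert mr.genus(torus) == 1

    def test_genus_sphere(self, icosphere3):
        assert mr.genus(icosphere3) == 0

    def test_genus_from_published_counts(self):
        # n_v=4824, n_e=14460, n_f=9640: E = 4, genus = -1 (a cavity)
        n_v, n_e, n_f = 4824, 14460, 9640
        E = n_v + n_f - n_e
        assert E == 4
        assert 1 - E // 2 == -1

    def test_nested_spheres_cavity_genus(self):
        outer = mr.make_icosphere(1, radius=2.0)
        inner = mr.make_icosphere(1, radius=1.0)
        # inner shell inverted so its normal points into the cavity
        inner_faces = inner.faces[:, ::-1] + outer.n_vertices
        m = mr.TriangleMesh(
            np.vstack([outer.vertices, inner.vertices]),
            np.vstack([outer.faces, inner_faces]),
        )
        assert mr.genus(m) == -1

    def test_genus_open_mesh_raises(self, grid_patch):
        with pytest.raises(NotClosedError):
            mr.genus(grid_patch)


class TestAreaVolume:
    def test_unit_cube(self, unit_cube):
        assert mr.surface_area(unit_cube) == pytest.approx(6.0)
        assert mr.enclosed_volume(unit_cube) == pytest.approx(1.0)

    def test_fine_sphere_closed_forms(self):
        r = 2.5
        s = mr.make_icosphere(4, radius=r)
        assert mr.surface_area(s) == pytest.approx(4 * math.pi * r * r, rel=0.01)
        assert mr.enclosed_volume(s) == pytest.approx(4 / 3 * math.pi * r**3, rel=0.01)

    def test_volume_translation_invariant(self, unit_cube):
        shifted = mr.TriangleMesh(unit_cube.vertices + [17.0, -4.0, 3.0],
                                  unit_cube.faces)
        assert mr.enclosed_volume(shifted) == pytest.approx(
            mr.enclosed_volume(unit_cube), abs=1e-12)

    def test_volume_orientation_tolerant(self, unit_cube):
        inverted = mr.TriangleMesh(unit_cube.vertices, unit_cube.faces[:, ::-1])
        assert mr.enclosed_volume(inverted) == pytest.approx(1.0)


class TestRegularVertices:
    def test_icosahedron_all_regular(self, icosahedron):
        assert mr.regular_vertex_ratio(icosahedron) == 100.0

    def test_matches_brute_force_valence_tally(self, grid_patch):
        got = mr.regular_vertex_ratio(grid_patch)
        # independent tally from raw faces
        n = grid_patch.n_vertices
        nbrs = [set() for _ in range(n)]
        for a, b, c in grid_patch.faces:
            nbrs[a] |= {b, c}
            nbrs[b] |= {a, c}
            nbrs[c] |= {a, b}
        boundary = set(grid_patch.boundary_edges.ravel().tolist())
        reg = 0
        for v in range(n):
            val = len(nbrs[v])
            reg += val in ((3, 4, 5) if v in boundary else (5, 6, 7))
        assert got == pytest.approx(100.0 * reg / n)

    def test_high_valence_fan_is_irregular(self):
        # 9-triangle closed fan: center vertex valence 9
        k = 9
        ring = [[math.cos(2 * math.pi * i / k), math.sin(2 * math.pi * i / k), 0]
                for i in range(k)]
        V = np.array([[0, 0, 0.2]] + ring + [[0, 0, -1.0]])
        F = [[0, 1 + i, 1 + (i + 1) % k] for i in range(k)]
        F += [[1 + (i + 1) % k, 1 + i, k + 1] for i in range(k)]
        m = mr.TriangleMesh(V, F)
        val = m.vertex_valence
        assert val[0] == 9
        ratio = mr.regular_vertex_ratio(m)
        assert ratio < 100.0


class TestSelfIntersections:
    def test_clean_icosphere_empty(self, icosphere3):
        assert mr.self_intersections(icosphere3) == []

    def test_interpenetrating_shells_match_oracle(self):
        s1 = mr.make_icosphere(0, radius=1.0)
        v2 = s1.vertices * 0.8 + [0.9, 0, 0]
        m = mr.TriangleMesh(
            np.vstack([s1.vertices, v2]),
            np.vstack([s1.faces, s1.faces + s1.n_vertices]),
        )
        got = mr.self_intersections(m)
        oracle = mr.self_intersections_brute_force(m)
        assert got == oracle
        assert len(got) > 0

    def test_shared_edge_not_reported(self):
        V = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]]
        F = [[0, 1, 2], [1, 3, 2]]
        assert mr.self_intersections(mr.TriangleMesh(V, F)) == []

    def test_coplanar_overlap_detected(self):
        V = [[0, 0, 0], [2, 0, 0], [0, 2, 0],
             [0.5, 0.5, 0], [2.5, 0.5, 0], [0.5, 2.5, 0]]
        F = [[0, 1, 2], [3, 4, 5]]
        m = mr.TriangleMesh(V, F)
        assert len(mr.self_intersections(m)) == 1

    def test_randomized_meshes_match_oracle(self, raw_fixture_small):
        assert (mr.self_intersections(raw_fixture_small)
                == mr.self_intersections_brute_force(raw_fixture_small))


class TestQualityReport:
    def test_icosahedron_report(self, icosahedron):
        rep = mr.quality_report(icosahedron)
        assert rep.theta_min == pytest.approx(60, abs=1e-9)
        assert rep.theta_max == pytest.approx(60, abs=1e-9)
        assert rep.pct_below_30 == 0.0
        assert rep.genus == 0
        assert rep.q_min == pytest.approx(1.0)
        assert rep.n_self_intersecting_pairs == 0

    def test_single_sliver_percentage(self):
        # 99 separate equilaterals + 1 sliver of min angle ~0.5 degrees
        tri = np.array([[0, 0, 0], [1, 0, 0], [0.5, math.sqrt(3) / 2, 0]])
        Vs, Fs = [], []
        for i in range(99):
            Vs.append(tri + [0, 0, 2.0 * i])
            Fs.append(np.array([[0, 1, 2]]) + 3 * i)
        sliver = np.array([[0, 0, -5], [1, 0, -5],
                           [0.5, 0.5 * math.tan(math.radians(0.5)), -5]])
        Vs.append(sliver)
        Fs.append(np.array([[0, 1, 2]]) + 3 * 99)
        m = mr.TriangleMesh(np.vstack(Vs), np.vstack(Fs))
        rep = mr.quality_report(m, count_intersections=False)
        assert rep.pct_below_30 == pytest.approx(1.0)

    def test_open_mesh_fields_undefined(self, grid_patch):
        rep = mr.quality_report(grid_patch, count_intersections=False)
        assert rep.genus is None
        assert rep.volume is None
        assert rep.theta_min <= rep.theta_min_mean <= 60 <= rep.theta_max

    def test_report_invariant_ordering(self, raw_fixture_small):
        rep = mr.quality_report(raw_fixture_small, count_intersections=False)
        assert 0 <= rep.q_min <= rep.q_avg <= 1
        assert 0 <= rep.theta_min <= rep.theta_min_mean <= 60 <= rep.theta_max <= 180
        assert (rep.pct_below_30 == 0) == (rep.theta_min >= 30)

    def test_serialization_undef_sentinel(self):
        m = mr.TriangleMesh([[0, 0, 0], [1, 0, 0], [2, 0, 0]], [[0, 1, 2]])
        rep = mr.quality_report(m, count_intersections=False)
        d = rep.to_dict()
        assert d["ar_max"] == "undef."
        csv = rep.to_csv()
        assert "undef." in csv and csv.count("\n") == 2
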