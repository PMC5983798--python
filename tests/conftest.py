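"""Shared fixtures: reference shapes and degraded molecular surfaces.

Everything is generated programmatically; the expensive pipeline runs are
session-scoped so the acceptance tests share one execution.
"""
from __future__ import annotations

import numpy as np
import pytest

import molremesh as mr
from molremesh import fixture_gen as fg


@pytest.fixture(scope="session")
def icosahedron() -> mr.TriangleMesh:
    return mr.make_icosphere(0)


@pytest.fixture(scope="session")
def icosphere3() -> mr.TriangleMesh:
    return mr.make_icosphere(3)


@pytest.fixture(scope="session")
def torus() -> mr.TriangleMesh:
    return mr.make_torus()


@pytest.fixture(scope="session")
def unit_cube() -> mr.TriangleMesh:
    import trimesh

    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return mr.TriangleMesh(np.asarray(box.vertices), np.asarray(box.faces))


def planar_grid(n: int = 5, spacing: float = 1.0) -> mr.TriangleMesh:
    """An open n x n right-triangle grid patch in the z = 0 plane."""
    xs = np.arange(n) * spacing
    V = np.array([[x, y, 0.0] for y in xs for x in xs])
    F = []
    for j in range(n - 1):
        for i in range(n - 1):
            a = j * n + i
            b = a + 1
            c = a + n
            d = c + 1
            F.append([a, b, d])
            F.append([a, d, c])
    return mr.TriangleMesh(V, np.array(F))


@pytest.fixture(scope="session")
def grid_patch() -> mr.TriangleMesh:
    return planar_grid(5)


@pytest.fixture(scope="session")
def clean_surface() -> mr.TriangleMesh:
    """Defect-free 5-atom Gaussian surface at reduced resolution."""
    return fg.extract_gaussian_surface(
        fg.default_atom_set(), fg.GaussianSurfaceSpec(resolution=1.5)
    )


@pytest.fixture(scope="session")
def raw_fixture_small() -> mr.TriangleMesh:
    """The degraded fixture at reduced resolution (< 2000 faces)."""
    return fg.default_raw_fixture(resolution=1.5)


@pytest.fixture(scope="session")
def pipeline_result_small(raw_fixture_small):
    """One shared full-pipeline run on the reduced fixture."""
    out, before, after = mr.remesh_molecular_surface(raw_fixture_small)
    return raw_fixture_small, out, before, after
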