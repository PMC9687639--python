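import numpy as np
import pytest
import trimesh

from sacisolate import FusiformSpec, SurfaceMesh, make_cylinder, make_fusiform


@pytest.fixture
def tetra_mesh() -> SurfaceMesh:
    """Regular tetrahedron surface: the smallest valid closed mesh."""
    nodes = np.array([
        [1.0, 1.0, 1.0],
        [1.0, -1.0, -1.0],
        [-1.0, 1.0, -1.0],
        [-1.0, -1.0, 1.0],
    ])
    tris = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
    return SurfaceMesh(nodes, tris, provenance="fixture:tetra")


@pytest.fixture
def icosahedron_mesh() -> SurfaceMesh:
    tm = trimesh.creation.icosahedron()
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces),
                       provenance="fixture:icosahedron")


@pytest.fixture
def icosphere_mesh() -> SurfaceMesh:
    tm = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces),
                       provenance="fixture:icosphere")


@pytest.fixture(scope="session")
def cylinder_mesh() -> SurfaceMesh:
    return make_cylinder(radius=10.0, length=100.0, axial_resolution=60,
                         circumferential_resolution=48)


@pytest.fixture(scope="session")
def fusiform_case():
    """Default symmetric-ish fusiform sac with ground truth, shared read-only."""
    spec = FusiformSpec(asymmetry=0.2)
    mesh, truth = make_fusiform(spec)
    return spec, mesh, truth
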