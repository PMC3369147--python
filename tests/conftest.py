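import numpy as np
import pytest
import trimesh

from hipcov.synthetic_hip import HipParams, generate_mesh, make_rim


@pytest.fixture(scope="session")
def default_params() -> HipParams:
    return HipParams()


@pytest.fixture(scope="session")
def default_femur(default_params):
    """One 12k-vertex synthetic femur mesh, shared across tests."""
    return generate_mesh(default_params)


@pytest.fixture(scope="session")
def default_rim(default_params):
    return make_rim(default_params)


@pytest.fixture(scope="session")
def sphere_mesh():
    """A 10242-vertex sphere of radius 24 mm centered at the origin."""
    return trimesh.creation.icosphere(subdivisions=4, radius=24.0)


def grid_cylinder(radius: float, height: float, n_theta: int = 96, n_z: int = 60):
    """Open parametric cylinder with roughly isotropic triangles (the
    trimesh primitive has degenerate full-height side triangles that break
    local curvature fits)."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    z = np.linspace(-height / 2.0, height / 2.0, n_z)
    tt, zz = np.meshgrid(theta, z, indexing="ij")
    verts = np.column_stack(
        [radius * np.cos(tt).ravel(), radius * np.sin(tt).ravel(), zz.ravel()]
    )
    faces = []
    for i in range(n_theta):
        for j in range(n_z - 1):
            a = i * n_z + j
            b = ((i + 1) % n_theta) * n_z + j
            faces.append([a, b, a + 1])
            faces.append([b, b + 1, a + 1])
    return trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
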