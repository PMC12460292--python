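import numpy as np
import pytest
import trimesh

import disctls as d


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def unit_cube_mesh():
    """Axis-aligned unit cube [0,1]³ as 12 consistently wound triangles."""
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    box.apply_translation((0.5, 0.5, 0.5))
    return box


@pytest.fixture()
def unit_tetrahedron_mesh():
    """Tetrahedron (0,0,0), (1,0,0), (0,1,0), (0,0,1); volume 1/6."""
    v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    mesh = trimesh.Trimesh(v, f, process=False)
    assert mesh.is_watertight
    return mesh


@pytest.fixture(scope="session")
def icosphere_mesh():
    return trimesh.creation.icosphere(subdivisions=4, radius=1.0)


@pytest.fixture(scope="session")
def sphere_cloud():
    """20k points uniform on the unit sphere with exact outward normals."""
    g = np.random.default_rng(7)
    p = g.normal(size=(20000, 3))
    p /= np.linalg.norm(p, axis=1, keepdims=True)
    return d.OrientedPointCloud(p, p.copy(), unit="m", id="sphere")


@pytest.fixture(scope="session")
def smooth_disc():
    """One smooth synthetic disc scan (study defaults: r=15 cm, h=5 cm,
    1000 pts/dm², three stations, occluded bottom, 1 mm noise)."""
    return d.generate_disc(d.DiscSpec(seed=1))


@pytest.fixture(scope="session")
def smooth_disc_result(smooth_disc):
    """The smooth disc pushed through fill → normals → reconstruct → volume.

    Session-scoped: the reconstruction is the expensive step and several
    tests assert different facets of the same run.
    """
    res = d.process_disc(smooth_disc.cloud)
    assert res.ok, res.error
    return res
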