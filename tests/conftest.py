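import numpy as np
import pytest
import trimesh

import pbdtissue as pt
from pbdtissue.io import TriangleMesh

TABLE_DEPTHS = (0.0, 5.95, 9.48, 12.38)


@pytest.fixture(scope="session")
def cube_mesh() -> TriangleMesh:
    """Closed 20 mm cube centred at the origin."""
    return TriangleMesh.from_trimesh(trimesh.creation.box(extents=(20.0, 20.0, 20.0)))


@pytest.fixture(scope="session")
def unit_tet_mesh() -> TriangleMesh:
    vertices = np.array(
        [[0.0, 0, 0], [1.0, 0, 0], [0.0, 1, 0], [0.0, 0, 1]]
    )
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriangleMesh(vertices=vertices, faces=faces, is_closed=True)


@pytest.fixture(scope="session")
def small_phantom() -> pt.PhantomScene:
    """Reduced organ (~350 particles at the default radius) for protocol runs."""
    return pt.make_phantom(size_mm=(80.0, 50.0, 32.0), seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_phantom) -> pt.SceneBundle:
    return pt.build_sim_scene(small_phantom, pt.SimulationConfig())


@pytest.fixture(scope="session")
def small_stages(small_phantom):
    return pt.make_stages(small_phantom, TABLE_DEPTHS)


@pytest.fixture(scope="session")
def small_reference(small_bundle, small_stages):
    """Reference fiducial trajectories simulated at a known stiffness 0.5."""
    return pt.make_reference(
        small_bundle, small_stages, pt.SimulationConfig(), alpha_true=0.5
    )
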