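import numpy as np
import pytest
import trimesh
from scipy.spatial.transform import Rotation

from pbdtissue.collision import (
    Contact,
    ConvexShape,
    PlaneShape,
    StaticMeshShape,
    detect_contacts,
    particle_particle_contacts,
    project_contact,
    project_particle_pair,
)
from pbdtissue.io import TriangleMesh


class TestPlane:
    def test_far_particle_no_contact(self):
        plane = PlaneShape((0, 0, 1), 0.0)
        contacts = detect_contacts([[0.0, 0, 5.0]], radius=1.0, shapes=[plane])
        assert contacts == []

    def test_penetrating_particle(self):
        plane = PlaneShape((0, 0, 1), 0.0)
        contacts = detect_contacts([[0.0, 0, 0.5]], radius=1.0, shapes=[plane])
        assert len(contacts) == 1
        c = contacts[0]
        assert np.allclose(c.normal, [0, 0, 1])
        assert c.depth == pytest.approx(0.5)

    def test_non_unit_normal_normalised(self):
        plane = PlaneShape((0, 0, 2.0), 4.0)  # z = 2 plane
        d, n, w = plane.signed_distance([[0.0, 0, 5.0]])
        assert d[0] == pytest.approx(3.0)
        assert np.allclose(w[0], [0, 0, 2.0])


class TestConvex:
    def test_interior_point_nearest_face(self):
        cube = ConvexShape.box(half_extents=(0.5, 0.5, 0.5))
        pt = np.array([[0.1, 0.0, 0.0]])
        d, n, _ = cube.signed_distance(pt)
        # brute force over the 6 half-spaces
        normals = np.vstack([np.eye(3), -np.eye(3)])
        offsets = np.full(6, 0.5)
        expected = max(normals @ pt[0] - offsets)
        assert d[0] == pytest.approx(expected)
        assert np.allclose(n[0], [1, 0, 0])
        contacts = detect_contacts(pt, radius=0.2, shapes=[cube])
        assert contacts[0].depth == pytest.approx(0.2 - expected)

    def test_exterior_corner_distance_exact(self):
        cube = ConvexShape.box(half_extents=(1.0, 1.0, 1.0))
        d, n, _ = cube.signed_distance([[2.0, 2.0, 2.0]])
        assert d[0] == pytest.approx(np.sqrt(3.0))
        assert np.allclose(n[0], np.ones(3) / np.sqrt(3.0))

    def test_posed_box(self):
        cube = ConvexShape.box(half_extents=(1.0, 2.0, 3.0))
        R = Rotation.from_rotvec([0, 0, np.pi / 2]).as_matrix()
        cube.set_pose(rotation=R, translation=(10.0, 0, 0))
        # after a 90° z-rotation the local y half-extent (2) lies along x
        d, _, _ = cube.signed_distance([[13.0, 0, 0]])
        assert d[0] == pytest.approx(1.0)

    def test_probe_pose_unchanged_by_contacts(self):
        cube = ConvexShape.box(half_extents=(1.0, 1.0, 1.0))
        cube.set_pose(translation=(0.0, 0, 0))
        before_t = cube.translation.copy()
        detect_contacts([[0.0, 0, 0.5]], radius=1.0, shapes=[cube])
        assert np.array_equal(cube.translation, before_t)


@pytest.fixture(scope="module")
def cube_shape():
    mesh = TriangleMesh.from_trimesh(trimesh.creation.box(extents=(2, 2, 2)))
    return StaticMeshShape(mesh)


class TestStaticMesh:
    def test_signed_distance_outside(self, cube_shape):
        d, n, w = cube_shape.signed_distance([[0.0, 0, 3.0]])
        assert d[0] == pytest.approx(2.0)
        assert np.allclose(n[0], [0, 0, 1])
        assert np.allclose(w[0], [0, 0, 1.0])

    def test_signed_distance_inside(self, cube_shape):
        d, n, _ = cube_shape.signed_distance([[0.0, 0, 0.6]])
        assert d[0] == pytest.approx(-0.4)
        assert np.allclose(n[0], [0, 0, 1])

    def test_corner_region_distance(self, cube_shape):
        d, _, w = cube_shape.signed_distance([[2.0, 2.0, 2.0]])
        assert d[0] == pytest.approx(np.sqrt(3.0))
        assert np.allclose(w[0], [1.0, 1.0, 1.0])

    def test_max_distance_culling(self, cube_shape):
        d, _, _ = cube_shape.signed_distance([[0.0, 0, 50.0]], max_distance=5.0)
        assert np.isinf(d[0])

    def test_pair_query_matches_full_query(self, cube_shape):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-2.5, 2.5, size=(200, 3))
        d_full, n_full, _ = cube_shape.signed_distance(pts)
        pi, ti = cube_shape.candidate_pairs(pts, 1.5)
        d_cut, n_cut, _ = cube_shape.signed_distance_from_pairs(pts, pi, ti)
        near = np.abs(d_full) < 1.5
        assert np.allclose(d_full[near], d_cut[near])
        assert np.allclose(n_full[near], n_cut[near])


class TestProjectContact:
    def test_pure_normal(self):
        c = Contact(particle=0, point=np.zeros(3), normal=np.array([0.0, 0, 1]),
                    depth=0.15, friction=0.25)
        delta = project_contact(c, np.zeros((1, 3)), np.ones(1))
        assert np.allclose(delta, [[0, 0, 0.15]])

    def test_coulomb_cap(self):
        c = Contact(particle=0, point=np.zeros(3), normal=np.array([0.0, 0, 1]),
                    depth=0.15, friction=0.25)
        slide = np.array([0.10, 0, 0])
        delta = project_contact(c, np.zeros((1, 3)), np.ones(1),
                                tangential_motion=slide)
        cap = 0.25 * 0.15
        assert delta[0, 0] == pytest.approx(-cap)  # min(0.10, 0.0375) = 0.0375
        assert delta[0, 2] == pytest.approx(0.15)

    def test_small_slide_fully_opposed(self):
        c = Contact(particle=0, point=np.zeros(3), normal=np.array([0.0, 0, 1]),
                    depth=0.15, friction=0.25)
        slide = np.array([0.01, 0, 0])
        delta = project_contact(c, np.zeros((1, 3)), np.ones(1),
                                tangential_motion=slide)
        assert delta[0, 0] == pytest.approx(-0.01)

    def test_zero_friction(self):
        c = Contact(particle=0, point=np.zeros(3), normal=np.array([0.0, 0, 1]),
                    depth=0.15, friction=0.0)
        delta = project_contact(c, np.zeros((1, 3)), np.ones(1),
                                tangential_motion=np.array([1.0, 0, 0]))
        assert np.allclose(delta, [[0, 0, 0.15]])

    def test_fixed_particle_not_moved(self):
        c = Contact(particle=0, point=np.zeros(3), normal=np.array([0.0, 0, 1]),
                    depth=0.15, friction=0.0)
        delta = project_contact(c, np.zeros((1, 3)), np.zeros(1))
        assert np.all(delta == 0)


class TestParticlePairs:
    def test_symmetric_split(self):
        x = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        pairs = particle_particle_contacts(x, radius=0.6)
        assert pairs == [(0, 1)]
        delta = project_particle_pair(0, 1, x, np.ones(2), radius=0.6)
        x_new = x + delta
        assert np.linalg.norm(x_new[0] - x_new[1]) == pytest.approx(1.2)
        assert np.allclose(x_new[0], [-0.1, 0, 0])

    def test_boundary_distance_excluded(self):
        x = np.array([[0.0, 0, 0], [1.2, 0, 0]])
        assert particle_particle_contacts(x, radius=0.6) == []

    def test_mass_weighted_split(self):
        x = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        delta = project_particle_pair(0, 1, x, np.array([0.0, 1.0]), radius=0.6)
        assert np.allclose(delta[0], 0)
        assert np.allclose(x[1] + delta[1], [1.2, 0, 0])

    def test_three_collinear_matches_slow_oracle(self):
        """Nine Jacobi iterations agree with an explicit-loop re-simulation."""
        from pbdtissue.io import SimulationConfig
        from pbdtissue.sampling import ParticleSet
        from pbdtissue.solver import Scene, Simulator

        radius = 0.6
        x0 = np.array([[0.0, 0, 0], [0.9, 0, 0], [1.8, 0, 0.0]])
        cfg = SimulationConfig(gravity=0.0, damping_factor=0.0, substeps=1,
                               iterations=9, particle_radius=radius)
        ps = ParticleSet(positions=x0, radius=radius, masses=np.ones(3))
        sim = Simulator(Scene(particles=ps, clusters=[]), cfg)
        sim.step()

        # independent slow oracle: same scheme, explicit python loops
        x = x0.copy()
        pairs = [(0, 1), (1, 2)]
        for _ in range(9):
            delta = np.zeros_like(x)
            counts = np.zeros(3)
            for i, j in pairs:
                diff = x[i] - x[j]
                dist = np.linalg.norm(diff)
                if dist >= 2 * radius or dist == 0:
                    continue
                n = diff / dist
                overlap = 2 * radius - dist
                counts[i] += 1
                counts[j] += 1
            n_pair = {}
            for i, j in pairs:
                n_pair[(i, j)] = max(counts[i], counts[j])
            for i, j in pairs:
                diff = x[i] - x[j]
                dist = np.linalg.norm(diff)
                if dist >= 2 * radius or dist == 0:
                    continue
                n = diff / dist
                overlap = 2 * radius - dist
                delta[i] += 0.5 * overlap * n / n_pair[(i, j)]
                delta[j] -= 0.5 * overlap * n / n_pair[(i, j)]
            x = x + delta
        assert np.abs(sim.state.x - x).max() < 1e-6

    def test_friction_dissipates_tangential_energy(self):
        from pbdtissue.io import SimulationConfig
        from pbdtissue.sampling import ParticleSet
        from pbdtissue.solver import Scene, Simulator

        cfg = SimulationConfig(gravity=0.0, damping_factor=0.0)
        ps = ParticleSet(positions=[[0.0, 0, 0.8]], radius=1.0, masses=[1.0])
        scene = Scene(particles=ps, clusters=[],
                      shapes=[PlaneShape((0, 0, 1), 0.0, friction=0.35)])
        sim = Simulator(scene, cfg)
        sim.state.v[:] = [50.0, 0, 0]
        e0 = 0.5 * (sim.state.v[0, :2] ** 2).sum()
        sim.step()
        e1 = 0.5 * (sim.state.v[0, :2] ** 2).sum()
        assert e1 < e0


class TestNoPenetrationAtRest:
    def test_resting_configuration_respects_radius(self):
        from pbdtissue.io import SimulationConfig
        from pbdtissue.sampling import ParticleSet
        from pbdtissue.solver import Scene, Simulator

        cfg = SimulationConfig()
        rng = np.random.default_rng(0)
        pos = np.column_stack(
            [rng.uniform(-5, 5, 9), rng.uniform(-5, 5, 9), np.full(9, 2.0)]
        )
        plane = PlaneShape((0, 0, 1), 0.0)
        ps = ParticleSet(positions=pos, radius=2.0, masses=np.ones(9))
        sim = Simulator(Scene(particles=ps, clusters=[], shapes=[plane]), cfg)
        for _ in range(30):
            sim.step()
        d, _, _ = plane.signed_distance(sim.state.x)
        assert d.min() >= 2.0 - 1e-6
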