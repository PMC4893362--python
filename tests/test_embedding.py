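import numpy as np
import pytest
import trimesh
from scipy.spatial.transform import Rotation

import pbdtissue as pt
from pbdtissue.embedding import (
    ScanPlane,
    bind_skin,
    build_tet_lattice,
    deform_points,
    embed_mesh,
    locate_barycentric,
    slice_ultrasound,
)
from pbdtissue.io import TriangleMesh
from pbdtissue.sampling import Cluster, contains_points


def make_clusters(origins):
    return [
        Cluster(
            member_indices=np.array([0]),
            rest_positions=np.asarray(o, dtype=float).reshape(1, 3),
            rest_com=np.asarray(o, dtype=float),
        )
        for o in origins
    ]


@pytest.fixture(scope="module")
def organ_setup():
    phantom = pt.make_phantom(size_mm=(60, 40, 30), seed=2)
    bundle = pt.build_sim_scene(phantom, pt.SimulationConfig())
    return phantom, bundle


class TestBindSkin:
    def test_point_on_origin_dominates(self):
        clusters = make_clusters([(0, 0, 0), (10, 0, 0), (0, 10, 0), (0, 0, 10), (5, 5, 5)])
        b = bind_skin([[0.0, 0, 0]], clusters)
        k = list(b.cluster_indices[0]).index(0)
        assert b.weights[0, k] > 1.0 - 1e-6

    def test_inverse_square_weights(self):
        clusters = make_clusters([(1.0, 0, 0), (2.0, 0, 0)])
        b = bind_skin([[0.0, 0, 0]], clusters)
        w = dict(zip(b.cluster_indices[0], b.weights[0]))
        assert w[0] == pytest.approx(0.8, abs=1e-6)
        assert w[1] == pytest.approx(0.2, abs=1e-6)

    def test_equidistant_symmetry(self):
        clusters = make_clusters([(1.0, 0, 0), (-1.0, 0, 0)])
        b = bind_skin([[0.0, 0, 0]], clusters)
        assert np.allclose(b.weights[0], [0.5, 0.5])

    def test_partition_of_unity_and_max_four(self, organ_setup):
        phantom, bundle = organ_setup
        b = bind_skin(phantom.fiducials.rest_positions, bundle.scene.clusters)
        assert b.cluster_indices.shape[1] <= 4
        assert np.abs(b.weights.sum(axis=1) - 1.0).max() < 1e-12
        assert (b.weights >= 0).all()


class TestDeformPoints:
    def test_rest_state_reproduces_points(self, organ_setup):
        phantom, bundle = organ_setup
        pts = phantom.fiducials.rest_positions
        b = bind_skin(pts, bundle.scene.clusters)
        out = deform_points(b, bundle.scene.clusters)
        assert np.abs(out - pts).max() < 1e-9

    def test_global_rigid_reproduction(self, organ_setup):
        phantom, bundle = organ_setup
        pts = phantom.fiducials.rest_positions
        b = bind_skin(pts, bundle.scene.clusters)
        Q = Rotation.from_rotvec([0.3, 0.2, 0.1]).as_matrix()
        t = np.array([5.0, 6.0, 7.0])
        for c in bundle.scene.clusters:
            c.rotation = Q
            c.com = Q @ c.rest_com + t
        out = deform_points(b, bundle.scene.clusters)
        assert np.abs(out - (pts @ Q.T + t)).max() < 1e-9
        for c in bundle.scene.clusters:  # restore shared fixture state
            c.rotation = np.eye(3)
            c.com = c.rest_com.copy()

    def test_single_cluster_tracks_frame(self):
        clusters = make_clusters([(0.0, 0, 0)])
        b = bind_skin([[1.0, 2, 3]], clusters)
        Q = Rotation.from_rotvec([0, 0, np.pi / 2]).as_matrix()
        clusters[0].rotation = Q
        clusters[0].com = np.array([10.0, 0, 0])
        out = deform_points(b, clusters)
        assert np.allclose(out[0], Q @ np.array([1.0, 2, 3]) + [10, 0, 0])


class TestTetLattice:
    def test_cube_single_cell_five_tets(self):
        mesh = TriangleMesh.from_trimesh(trimesh.creation.box(extents=(10, 10, 10)))
        vertices, tets = build_tet_lattice(mesh, spacing=10.0)
        assert len(tets) == 5
        v = vertices[tets]
        vol = np.einsum(
            "ij,ij->i",
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]),
            v[:, 3] - v[:, 0],
        ).sum() / 6.0
        assert vol == pytest.approx(1000.0)

    def test_lattice_covers_mesh_volume(self, organ_setup):
        phantom, _ = organ_setup
        vertices, tets = build_tet_lattice(phantom.organ, spacing=10.0)
        v = vertices[tets]
        vol = np.abs(
            np.einsum(
                "ij,ij->i",
                np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]),
                v[:, 3] - v[:, 0],
            )
        ).sum() / 6.0
        assert vol >= phantom.organ.volume()

    def test_interior_points_located_uniquely(self, organ_setup):
        phantom, _ = organ_setup
        vertices, tets = build_tet_lattice(phantom.organ, spacing=10.0)
        rng = np.random.default_rng(0)
        pts = rng.uniform(-1, 1, (2000, 3)) * (phantom.semi_axes - 0.5)
        pts = pts[contains_points(phantom.organ, pts)][:300]
        tid, bary = locate_barycentric(pts, vertices, tets)
        assert (tid >= 0).all()
        # strict multiplicity: random interior points lie in exactly one tet
        tv = vertices[tets]
        M = np.stack(
            [tv[:, 1] - tv[:, 0], tv[:, 2] - tv[:, 0], tv[:, 3] - tv[:, 0]], axis=2
        )
        Minv = np.linalg.inv(M)
        for p in pts[:50]:
            b123 = np.einsum("tij,tj->ti", Minv, p - tv[:, 0])
            full = np.column_stack([1 - b123.sum(1), b123])
            strict = (full > 1e-9).all(axis=1)
            assert strict.sum() == 1

    def test_bad_spacing_rejected(self, organ_setup):
        phantom, _ = organ_setup
        with pytest.raises(ValueError):
            build_tet_lattice(phantom.organ, spacing=1000.0)


class TestLocateBarycentric:
    UNIT_TET_V = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1, 0], [0.0, 0, 1]])
    UNIT_TET = np.array([[0, 1, 2, 3]])

    def test_centroid(self):
        tid, b = locate_barycentric([[0.25, 0.25, 0.25]], self.UNIT_TET_V, self.UNIT_TET)
        assert tid[0] == 0
        assert np.allclose(b[0], 0.25)

    def test_vertex(self):
        tid, b = locate_barycentric([[0.0, 0, 0]], self.UNIT_TET_V, self.UNIT_TET)
        assert tid[0] == 0
        assert np.allclose(b[0], [1, 0, 0, 0])

    def test_outside_is_background(self):
        tid, _ = locate_barycentric([[2.0, 2, 2]], self.UNIT_TET_V, self.UNIT_TET)
        assert tid[0] == -1

    def test_round_trip_reconstruction(self, organ_setup):
        phantom, _ = organ_setup
        vertices, tets = build_tet_lattice(phantom.organ, spacing=8.0)
        rng = np.random.default_rng(1)
        pts = rng.uniform(-1, 1, (500, 3)) * (phantom.semi_axes - 1.0)
        pts = pts[contains_points(phantom.organ, pts)][:100]
        tid, bary = locate_barycentric(pts, vertices, tets)
        assert (tid >= 0).all()
        assert np.abs(bary.sum(axis=1) - 1.0).max() < 1e-12
        rec = (bary[:, :, None] * vertices[tets[tid]]).sum(axis=1)
        assert np.abs(rec - pts).max() < 1e-9


class TestSliceUltrasound:
    @pytest.fixture(scope="class")
    def sliced(self):
        phantom = pt.make_phantom(size_mm=(60, 40, 30), seed=2)
        bundle = pt.build_sim_scene(phantom, pt.SimulationConfig())
        emb = embed_mesh(phantom.organ, bundle.scene.clusters, spacing=10.0)
        plane = ScanPlane(origin=(-30, -2, -15), axis_u=(1, 0, 0),
                          axis_v=(0, 0, 1), extent=(60, 30), pitch=1.0)
        return phantom, emb, plane

    def test_undeformed_equals_direct_resampling(self, sliced):
        phantom, emb, plane = sliced
        img, mask = slice_ultrasound(plane, emb, phantom.volume, return_mask=True)
        direct = phantom.volume.sample_trilinear(
            plane.pixel_centres().reshape(-1, 3)
        ).reshape(img.shape)
        assert mask.sum() > 100
        assert np.abs(img - direct)[mask].max() < 1e-9

    def test_constant_volume_gives_constant(self, sliced):
        phantom, emb, plane = sliced
        const = pt.VolumeImage(
            voxels=np.full_like(phantom.volume.voxels, 7, dtype=np.int16),
            spacing=phantom.volume.spacing,
            origin=phantom.volume.origin,
        )
        img, mask = slice_ultrasound(plane, emb, const, return_mask=True)
        assert np.allclose(img[mask], 7.0)

    def test_rigid_translation_pull_back(self, sliced):
        phantom, emb, plane = sliced
        tvec = np.array([3.0, -2.0, 1.5])
        img, mask = slice_ultrasound(
            plane, emb, phantom.volume,
            deformed_vertices=emb.rest_vertices + tvec, return_mask=True,
        )
        shifted = ScanPlane(
            origin=plane.origin - tvec, axis_u=plane.axis_u,
            axis_v=plane.axis_v, extent=plane.extent, pitch=plane.pitch,
        )
        direct = phantom.volume.sample_trilinear(
            shifted.pixel_centres().reshape(-1, 3)
        ).reshape(img.shape)
        assert np.abs(img - direct)[mask].max() < 1e-9

    def test_pgm_export_round_trip(self, sliced, tmp_path):
        import json

        from pbdtissue.embedding import save_slice_pgm

        phantom, emb, plane = sliced
        img = slice_ultrasound(plane, emb, phantom.volume)
        path = tmp_path / "slice.pgm"
        save_slice_pgm(img, path, plane)
        lines = path.read_text().splitlines()
        assert lines[0] == "P2"
        w, h = map(int, lines[1].split())
        assert (w, h) == (img.shape[1], img.shape[0])
        sidecar = json.loads((tmp_path / "slice.pgm.json").read_text())
        assert sidecar["pitch_mm"] == plane.pitch
        assert np.allclose(sidecar["origin_mm"], plane.origin)

    def test_plane_outside_gives_background(self, sliced):
        phantom, emb, _ = sliced
        far = ScanPlane(origin=(500, 500, 500), axis_u=(1, 0, 0),
                        axis_v=(0, 1, 0), extent=(10, 10), pitch=1.0)
        img, mask = slice_ultrasound(far, emb, phantom.volume,
                                     background=-1.0, return_mask=True)
        assert not mask.any()
        assert np.all(img == -1.0)
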