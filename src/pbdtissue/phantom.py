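"""Synthetic kidney-scale test scene: organ, support, probe, beads, volume.

The phantom emulates the bench configuration the simulator is calibrated
against: a smooth organ-scale body resting in a shallow concave support,
indented from above by a cuboid probe, with ~45 fiducial beads threaded
through the interior and a synthetic CT volume containing internal
structures of distinct intensity.  An ellipsoid stands in for the kidney:
it preserves the scale, smoothness and concave support contact that the
deformation mechanics exercise, without claiming anatomical fidelity.

Scene generation is pure: the parameters and seed fully determine the
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .collision import ConvexShape, PlaneShape, StaticMeshShape
from .embedding import SkinBinding, bind_skin, deform_points
from .io import FiducialSet, SimulationConfig, TriangleMesh, VolumeImage
from .sampling import assign_masses, build_clusters, sample_particles
from .solver import Scene

__all__ = [
    "PhantomScene",
    "SceneBundle",
    "make_phantom",
    "make_stages",
    "make_reference",
    "build_sim_scene",
]

_FIDUCIAL_MARGIN = 3.0  # mm clearance between beads and the organ surface
_PROBE_HALF_EXTENTS = np.array([12.0, 8.0, 15.0])  # mm; transducer-head cuboid
_SUPPORT_THICKNESS = 15.0  # mm slab below the dish surface
_SUPPORT_DISH_DEPTH = 8.0  # mm rise of the dish rim above its centre


@dataclass
class DeformationStage:
    """One probe pose of the staged indentation protocol."""

    index: int
    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,) mm
    depth: float  # cumulative indentation along the probe axis, mm


@dataclass
class PhantomScene:
    organ: TriangleMesh
    support: TriangleMesh
    probe_half_extents: np.ndarray
    probe_rest_translation: np.ndarray  # stage-0 (tangent) pose, identity rotation
    probe_axis: np.ndarray  # unit inward indentation direction
    fiducials: FiducialSet
    volume: VolumeImage
    semi_axes: np.ndarray
    seed: int


def _ellipsoid_mesh(semi_axes: np.ndarray, subdivisions: int = 3) -> TriangleMesh:
    sphere = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    vertices = np.asarray(sphere.vertices) * semi_axes
    return TriangleMesh(
        vertices=vertices, faces=np.asarray(sphere.faces), is_closed=True
    )


def _support_mesh(semi_axes: np.ndarray, surface_offset: float) -> TriangleMesh:
    """Closed slab whose top is a shallow mould of the organ's lower surface.

    Emulates a plasticine bed pressed against the organ: the cup follows the
    ellipsoid's lower surface (clipped to a shallow depth so the organ is
    cradled, not trapped), offset outward by ``surface_offset`` so that the
    particle centres representing the organ rest on it without initial
    penetration.
    """
    a, b, c = semi_axes
    half_x, half_y = 1.3 * a, 1.6 * b
    n = 21
    xs = np.linspace(-half_x, half_x, n)
    ys = np.linspace(-half_y, half_y, n)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    r2 = (gx / a) ** 2 + (gy / b) ** 2
    z_ell = -c * np.sqrt(np.clip(1.0 - r2, 0.0, None))
    # the offset is applied along the local surface normal, so the vertical
    # drop is offset / |n_z| (clipped on steep flanks, where the cup is
    # truncated anyway)
    nz = np.where(
        r2 < 1.0,
        np.abs(z_ell / c**2)
        / np.sqrt((gx / a**2) ** 2 + (gy / b**2) ** 2 + (z_ell / c**2) ** 2 + 1e-30),
        1.0,
    )
    rim = -c + _SUPPORT_DISH_DEPTH  # cup depth below the rim
    z_top = np.minimum(z_ell, rim) - surface_offset / np.clip(nz, 0.35, 1.0)
    z_bot = float(z_top.min()) - _SUPPORT_THICKNESS

    top = np.stack([gx, gy, z_top], axis=-1).reshape(-1, 3)
    bottom = np.stack([gx, gy, np.full_like(gx, z_bot)], axis=-1).reshape(-1, 3)
    vertices = np.vstack([top, bottom])
    nb = len(top)

    def tid(i, j):
        return i * n + j

    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            q = [tid(i, j), tid(i + 1, j), tid(i + 1, j + 1), tid(i, j + 1)]
            faces.append([q[0], q[1], q[2]])  # top, outward = +z-ish
            faces.append([q[0], q[2], q[3]])
            faces.append([nb + q[0], nb + q[2], nb + q[1]])  # bottom, -z
            faces.append([nb + q[0], nb + q[3], nb + q[2]])
    # side walls along the four boundary strips, subdivided vertically so no
    # triangle is much larger than the top-surface ones
    borders = (
        [tid(0, j) for j in range(n)],
        [tid(i, n - 1) for i in range(n)],
        [tid(n - 1, j) for j in range(n - 1, -1, -1)],
        [tid(i, 0) for i in range(n - 1, -1, -1)],
    )
    vertices = [vertices]
    n_sub = 3
    next_vid = 2 * nb
    for strip in borders:
        top_ids = strip
        prev_row = list(top_ids)
        for level in range(1, n_sub):
            t = level / n_sub
            row = []
            for u in top_ids:
                p_top = vertices[0][u]
                p_bot = np.array([p_top[0], p_top[1], z_bot])
                vertices.append(((1 - t) * p_top + t * p_bot).reshape(1, 3))
                row.append(next_vid)
                next_vid += 1
            for k in range(len(strip) - 1):
                faces.append([prev_row[k], row[k], row[k + 1]])
                faces.append([prev_row[k], row[k + 1], prev_row[k + 1]])
            prev_row = row
        for k in range(len(strip) - 1):
            u, v = strip[k], strip[k + 1]
            faces.append([prev_row[k], nb + u, nb + v])
            faces.append([prev_row[k], nb + v, prev_row[k + 1]])
    vertices = np.vstack(vertices)
    mesh = trimesh.Trimesh(vertices=vertices, faces=np.asarray(faces), process=False)
    mesh.merge_vertices()
    mesh.fix_normals()
    return TriangleMesh.from_trimesh(mesh)


def _inside_shrunk_ellipsoid(points: np.ndarray, semi_axes, margin: float):
    s = np.asarray(semi_axes, dtype=float) - margin
    return ((np.atleast_2d(points) / s) ** 2).sum(axis=1) <= 1.0


def _sample_interior(rng, semi_axes, margin, n):
    s = np.asarray(semi_axes, dtype=float) - margin
    out = []
    while len(out) < n:
        cand = rng.uniform(-1.0, 1.0, size=(4 * n, 3))
        keep = (cand**2).sum(axis=1) <= 1.0
        out.extend(cand[keep] * s)
    return np.asarray(out[:n])


def _fiducial_threads(
    rng: np.random.Generator,
    semi_axes: np.ndarray,
    n_fiducials: int,
    n_threads: int,
) -> np.ndarray:
    """Beads along thread-like interior chords, jitter-spaced, margin-safe.

    Each thread is a straight chord between two interior points of the
    margin-shrunk ellipsoid; beads between interior endpoints stay interior
    by convexity.
    """
    per_thread = np.full(n_threads, n_fiducials // n_threads)
    per_thread[: n_fiducials % n_threads] += 1
    beads = []
    for k in range(n_threads):
        nb = int(per_thread[k])
        if nb == 0:
            continue
        for _ in range(100):
            ends = _sample_interior(rng, semi_axes, _FIDUCIAL_MARGIN, 2)
            if np.linalg.norm(ends[1] - ends[0]) > 0.4 * semi_axes.min():
                break
        else:  # pragma: no cover - extremely unlikely
            raise RuntimeError("could not place a fiducial thread")
        t = (np.arange(nb) + 0.5) / nb
        t = np.clip(t + rng.uniform(-0.25, 0.25, size=nb) / nb, 0.0, 1.0)
        beads.append(ends[0] + t[:, None] * (ends[1] - ends[0]))
    return np.vstack(beads)


def _synthetic_volume(semi_axes: np.ndarray, spacing: float = 1.0) -> VolumeImage:
    """Background plus two nested ellipsoidal compartments (distinct levels)."""
    pad = 5.0
    lo = -(semi_axes + pad)
    hi = semi_axes + pad
    axes = [np.arange(lo[k], hi[k] + spacing, spacing) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    r2 = (gx / semi_axes[0]) ** 2 + (gy / semi_axes[1]) ** 2 + (gz / semi_axes[2]) ** 2
    voxels = np.zeros(gx.shape, dtype=np.int16)
    voxels[r2 <= 1.0] = 120  # parenchyma analogue
    inner = np.array([0.45, 0.5, 0.5]) * semi_axes
    centre = np.array([0.25 * semi_axes[0], 0.0, 0.0])
    r2_in = (
        ((gx - centre[0]) / inner[0]) ** 2
        + ((gy - centre[1]) / inner[1]) ** 2
        + ((gz - centre[2]) / inner[2]) ** 2
    )
    voxels[r2_in <= 1.0] = 240  # collecting-system analogue
    origin = np.array([axes[0][0], axes[1][0], axes[2][0]])
    return VolumeImage(voxels=voxels, spacing=np.full(3, spacing), origin=origin)


def make_phantom(
    size_mm=(110.0, 60.0, 40.0),
    n_fiducials: int = 45,
    n_threads: int = 6,
    seed: int = 0,
    support_offset_mm: float = 2.7,
) -> PhantomScene:
    """Deterministic synthetic scene at kidney scale.

    ``size_mm`` are the full organ axis lengths; the defaults give the
    ~110 × 60 × 40 mm envelope of a porcine kidney.  Fiducials are kept at
    least ~3 mm inside the surface.  ``support_offset_mm`` should match the
    collision-particle radius so the organ's particle representation starts
    resting on the support mould without penetration.
    """
    if n_fiducials < 1:
        raise ValueError("need at least one fiducial")
    semi = np.asarray(size_mm, dtype=float) / 2.0
    if np.any(semi <= _FIDUCIAL_MARGIN + 1.0):
        raise ValueError("organ too small to hold interior fiducials")
    rng = np.random.default_rng(seed)
    organ = _ellipsoid_mesh(semi)
    support = _support_mesh(semi, support_offset_mm)
    beads = _fiducial_threads(rng, semi, n_fiducials, n_threads)
    fiducials = FiducialSet(
        labels=[f"F{i:02d}" for i in range(len(beads))], rest_positions=beads
    )
    volume = _synthetic_volume(semi)
    probe_axis = np.array([0.0, 0.0, -1.0])
    rest_translation = np.array([0.0, 0.0, semi[2] + _PROBE_HALF_EXTENTS[2]])
    return PhantomScene(
        organ=organ,
        support=support,
        probe_half_extents=_PROBE_HALF_EXTENTS.copy(),
        probe_rest_translation=rest_translation,
        probe_axis=probe_axis,
        fiducials=fiducials,
        volume=volume,
        semi_axes=semi,
        seed=seed,
    )


def make_stages(scene: PhantomScene, depths_mm) -> list[DeformationStage]:
    """Probe poses for a staged indentation protocol.

    Stage 0 (depth 0) is tangent to the organ surface along the probe axis;
    stage k is the tangent pose translated ``depths_mm[k]`` inward.  Poses
    differ only by translation along the probe axis.
    """
    depths = np.asarray(depths_mm, dtype=float)
    if depths[0] != 0.0 or np.any(np.diff(depths) < 0):
        raise ValueError("depths must be non-decreasing and start at 0")
    if depths[-1] >= 2.0 * scene.semi_axes[2]:
        raise ValueError("indentation exceeds the organ thickness")
    stages = []
    for k, depth in enumerate(depths):
        stages.append(
            DeformationStage(
                index=k,
                rotation=np.eye(3),
                translation=scene.probe_rest_translation
                + depth * scene.probe_axis,
                depth=float(depth),
            )
        )
    return stages


@dataclass
class SceneBundle:
    """A solver-ready scene plus the skinned fiducials of a phantom."""

    scene: Scene
    fiducial_binding: SkinBinding
    fiducials: FiducialSet
    phantom: PhantomScene
    surface_binding: SkinBinding | None = None

    def fiducial_positions(self) -> np.ndarray:
        """Current skinned fiducial positions under the cluster states."""
        return deform_points(self.fiducial_binding, self.scene.clusters)


def build_sim_scene(
    phantom: PhantomScene,
    config: SimulationConfig,
    bind_surface: bool = False,
) -> SceneBundle:
    """Sample particles and clusters from the phantom and assemble the scene.

    The support is a static mesh obstacle; a static floor plane at the
    support base acts as a safety boundary condition; the probe is a
    kinematic cuboid at its stage-0 (tangent) pose.
    """
    r = config.particle_radius
    particles = sample_particles(
        phantom.organ,
        radius=r,
        volume_sampling_factor=config.volume_sampling_factor,
        seed=phantom.seed,
    )
    particles = assign_masses(
        particles, phantom.organ.volume(), config.density_g_mm3
    )
    clusters = build_clusters(
        particles, r, config.cluster_spacing_factor, stiffness=config.alpha
    )
    support_shape = StaticMeshShape(phantom.support, friction=config.shape_friction)
    floor_z = float(phantom.support.vertices[:, 2].min())
    floor = PlaneShape(
        normal=(0.0, 0.0, 1.0), offset=floor_z, friction=config.shape_friction
    )
    probe = ConvexShape.box(
        phantom.probe_half_extents, friction=config.shape_friction
    )
    probe.set_pose(rotation=np.eye(3), translation=phantom.probe_rest_translation)
    scene = Scene(
        particles=particles,
        clusters=clusters,
        shapes=[support_shape, floor],
        probe=probe,
    )
    fid_binding = bind_skin(phantom.fiducials.rest_positions, clusters)
    surf_binding = (
        bind_skin(phantom.organ.vertices, clusters) if bind_surface else None
    )
    return SceneBundle(
        scene=scene,
        fiducial_binding=fid_binding,
        fiducials=phantom.fiducials,
        phantom=phantom,
        surface_binding=surf_binding,
    )


def make_reference(
    bundle: SceneBundle,
    stages: list[DeformationStage],
    config: SimulationConfig,
    alpha_true: float,
    warmup_steps: int = 120,
    interp_steps: int = 90,
) -> list[np.ndarray]:
    """Forward-simulate the protocol at a known stiffness.

    The recorded per-stage skinned fiducial positions stand in for segmented
    ground-truth fiducials in calibration experiments.
    """
    from .calibration import run_stage_protocol

    return run_stage_protocol(
        bundle,
        stages,
        config,
        alpha=alpha_true,
        warmup_steps=warmup_steps,
        interp_steps=interp_steps,
    )
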