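"""Reading and writing of external formats and the run configuration.

All geometry is kept in a millimetre / gram / second unit system internally:
CT volumes and surgical meshes are naturally expressed in millimetres, and a
single consistent small-scale system avoids tolerance bugs when mixing
surface geometry with image metadata.  User-facing configuration values keep
the conventional units they are usually quoted in (gravity in m/s², tissue
density in g/cm³) and are converted on access.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk
import trimesh

__all__ = [
    "TriangleMesh",
    "VolumeImage",
    "FiducialSet",
    "SimulationConfig",
    "read_surface_mesh",
    "write_surface_mesh",
    "read_volume",
    "write_volume",
    "read_fiducials",
    "write_fiducials",
    "load_config",
    "dump_config",
]

# unit conversions applied at the config boundary
M_PER_S2_TO_MM_PER_S2 = 1.0e3
G_PER_CM3_TO_G_PER_MM3 = 1.0e-3


@dataclass
class TriangleMesh:
    """A triangular surface mesh with vertices in millimetres.

    ``is_closed`` is true when every edge is shared by exactly two faces
    (watertight), which organ meshes must satisfy for interior sampling.
    """

    vertices: np.ndarray  # (n, 3) float, mm
    faces: np.ndarray  # (m, 3) int, 0-based
    is_closed: bool = False

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face index out of range")

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh) -> "TriangleMesh":
        return cls(
            vertices=np.asarray(mesh.vertices, dtype=float),
            faces=np.asarray(mesh.faces, dtype=np.int64),
            is_closed=bool(mesh.is_watertight),
        )

    @property
    def bounds(self) -> np.ndarray:
        """(2, 3) min/max corner of the axis-aligned bounding box, mm."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def volume(self) -> float:
        """Enclosed volume in mm³ (requires a closed, oriented mesh)."""
        tm = self.to_trimesh()
        return float(abs(tm.volume))


@dataclass
class VolumeImage:
    """A 3-D scalar image with voxel-centre anchored affine metadata.

    ``origin`` is the world position (mm) of the centre of voxel (0, 0, 0);
    indices are 0-based and the world↔voxel map is the diagonal affine
    ``world = origin + spacing * index`` (axis-aligned volumes only, which
    covers synthetic CT and resampled acquisitions).
    """

    voxels: np.ndarray  # (nx, ny, nz)
    spacing: np.ndarray  # (3,) mm/voxel
    origin: np.ndarray  # (3,) mm

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("volume must be 3-D")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return self.origin + idx * self.spacing

    def world_to_voxel(self, pos: np.ndarray) -> np.ndarray:
        pos = np.asarray(pos, dtype=float)
        return (pos - self.origin) / self.spacing

    def sample_trilinear(
        self, points: np.ndarray, outside_value: float = 0.0
    ) -> np.ndarray:
        """Trilinear intensity at world points (mm); outside → sentinel."""
        from scipy.ndimage import map_coordinates

        pts = np.atleast_2d(np.asarray(points, dtype=float))
        coords = self.world_to_voxel(pts).T  # (3, n)
        return map_coordinates(
            self.voxels.astype(float),
            coords,
            order=1,
            mode="constant",
            cval=outside_value,
        )


@dataclass
class FiducialSet:
    """Labelled fiducial bead positions (mm), optionally per deformation stage."""

    labels: list[str]
    rest_positions: np.ndarray  # (n, 3) mm
    observed_positions: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rest_positions = np.asarray(self.rest_positions, dtype=float).reshape(
            -1, 3
        )
        if len(self.labels) != len(self.rest_positions):
            raise ValueError("one rest position per label required")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class SimulationConfig:
    """Solver settings, mirroring the calibration run configuration.

    Fields keep their conventional quotation units (``gravity`` in m/s²,
    ``density`` in g/cm³); the ``*_internal`` properties convert to the
    mm-g-s system the solver uses.
    """

    dt: float = 1.0 / 60.0  # s
    substeps: int = 3
    iterations: int = 9
    cluster_spacing_factor: float = 3.33
    volume_sampling_factor: float = 4.0
    relaxation_mode: str = "local"  # "local" | "global"
    relaxation_factor: float = 1.0  # w; in [1, 2] for global SOR
    gravity: float = 9.81  # m/s², magnitude, acting along -z
    density: float = 1.05  # g/cm³
    shape_friction: float = 0.35
    particle_friction: float = 0.25
    damping_factor: float = 12.0  # 1/s exponential velocity decay rate
    particle_radius: float = 2.7  # mm
    alpha: float = 0.5  # cluster stiffness in [0, 1]

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.substeps < 1 or self.iterations < 1:
            raise ValueError("substeps and iterations must be >= 1")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.relaxation_mode not in ("local", "global"):
            raise ValueError("relaxation_mode must be 'local' or 'global'")
        if self.relaxation_mode == "global" and not (
            1.0 <= self.relaxation_factor <= 2.0
        ):
            raise ValueError("global relaxation factor w must lie in [1, 2]")

    @property
    def substep_dt(self) -> float:
        return self.dt / self.substeps

    @property
    def gravity_mm_s2(self) -> np.ndarray:
        """Gravity acceleration vector in mm/s² (acts along -z)."""
        return np.array([0.0, 0.0, -self.gravity * M_PER_S2_TO_MM_PER_S2])

    @property
    def density_g_mm3(self) -> float:
        return self.density * G_PER_CM3_TO_G_PER_MM3

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def read_surface_mesh(path: str | Path) -> TriangleMesh:
    """Read an STL or OBJ surface mesh; duplicate vertices are welded."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    loaded = trimesh.load(str(path), force="mesh", process=True)
    if not isinstance(loaded, trimesh.Trimesh) or len(loaded.faces) == 0:
        raise ValueError(f"no triangular faces found in {path}")
    loaded.merge_vertices()
    return TriangleMesh.from_trimesh(loaded)


def write_surface_mesh(mesh: TriangleMesh, path: str | Path) -> None:
    mesh.to_trimesh().export(str(path))


def read_volume(path: str | Path) -> VolumeImage:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume.

    Only axis-aligned orientations are supported: the affine must be a
    positive diagonal scaling plus translation.
    """
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        affine = img.affine
        voxels = np.asarray(img.dataobj)
    elif name.endswith((".mha", ".mhd")):
        img = sitk.ReadImage(str(path))
        # SimpleITK arrays come back (z, y, x); transpose to (x, y, z)
        voxels = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        direction = np.asarray(img.GetDirection()).reshape(3, 3)
        affine = np.eye(4)
        affine[:3, :3] = direction * np.asarray(img.GetSpacing())
        affine[:3, 3] = img.GetOrigin()
    else:
        raise ValueError(f"unsupported volume format: {path}")
    linear = affine[:3, :3]
    if not np.allclose(linear, np.diag(np.diag(linear))):
        raise ValueError("only axis-aligned volume orientations are supported")
    spacing = np.diag(linear)
    if np.any(spacing <= 0):
        raise ValueError("volume affine is not invertible / positively oriented")
    return VolumeImage(voxels=voxels, spacing=spacing, origin=affine[:3, 3])


def write_volume(volume: VolumeImage, path: str | Path) -> None:
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        affine = np.eye(4)
        affine[:3, :3] = np.diag(volume.spacing)
        affine[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(volume.voxels, affine), str(path))
    elif name.endswith((".mha", ".mhd")):
        img = sitk.GetImageFromArray(volume.voxels.transpose(2, 1, 0))
        img.SetSpacing(tuple(float(s) for s in volume.spacing))
        img.SetOrigin(tuple(float(o) for o in volume.origin))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported volume format: {path}")


def read_fiducials(path: str | Path) -> FiducialSet:
    """Read fiducials from CSV with header ``label,x,y,z`` (mm)."""
    df = pd.read_csv(path)
    required = {"label", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"fiducial CSV must have columns {sorted(required)}")
    return FiducialSet(
        labels=[str(v) for v in df["label"]],
        rest_positions=df[["x", "y", "z"]].to_numpy(dtype=float),
    )


def write_fiducials(fiducials: FiducialSet, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "label": fiducials.labels,
            "x": fiducials.rest_positions[:, 0],
            "y": fiducials.rest_positions[:, 1],
            "z": fiducials.rest_positions[:, 2],
        }
    )
    df.to_csv(path, index=False)


def load_config(path: str | Path) -> SimulationConfig:
    """Load a JSON run configuration; missing keys take the defaults."""
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise ValueError("config JSON must be an object")
    return SimulationConfig.from_dict(data)


def dump_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)
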