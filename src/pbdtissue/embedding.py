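"""Skinning of auxiliary geometry to cluster frames and deformable reslicing.

Surface vertices and fiducials follow the particle system through weighted
matrix blending ("skinning"): each point is attached to its four nearest
cluster frames with weights falling off as the inverse square of the distance
to the cluster origin, and its deformed position is the weighted blend of the
clusters' rigid transforms applied to the rest offset.

A coarse tetrahedral lattice embedded in the same way carries the simulated
2D ultrasound plane: each pixel of the plane is located barycentrically in
the *deformed* tetrahedra and pulled back with the same barycentric weights
to the *rest* configuration, where the preoperative volume is sampled
trilinearly.  This realises ultrasound scanning of the deforming organ using
the original acquisition as the data source, with no acoustic modelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .collision import StaticMeshShape
from .io import TriangleMesh, VolumeImage

__all__ = [
    "SkinBinding",
    "TetraEmbedding",
    "ScanPlane",
    "bind_skin",
    "deform_points",
    "build_tet_lattice",
    "embed_mesh",
    "locate_barycentric",
    "slice_ultrasound",
    "save_slice_pgm",
]

_WEIGHT_EPS = 1e-6  # mm², regularises the inverse-square weight at zero distance


@dataclass
class SkinBinding:
    """Per-point attachment to up to four cluster frames.

    ``offsets[i, k]`` is the rest position of point i relative to the rest
    centre of mass of cluster ``cluster_indices[i, k]``; weights are
    non-negative and sum to one per point.
    """

    cluster_indices: np.ndarray  # (n, k<=4) int
    weights: np.ndarray  # (n, k)
    offsets: np.ndarray  # (n, k, 3) mm


@dataclass
class ScanPlane:
    """Planar discretisation of the ultrasound scanning plane.

    ``origin`` is the corner of the imaged rectangle; ``axis_u``/``axis_v``
    are orthonormal in-plane directions; ``extent`` is the physical size
    (mm) along (u, v) and ``pitch`` the pixel spacing (mm).
    """

    origin: np.ndarray
    axis_u: np.ndarray
    axis_v: np.ndarray
    extent: tuple[float, float]
    pitch: float

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axis_u = np.asarray(self.axis_u, dtype=float).reshape(3)
        self.axis_v = np.asarray(self.axis_v, dtype=float).reshape(3)
        for a in (self.axis_u, self.axis_v):
            n = np.linalg.norm(a)
            if abs(n - 1.0) > 1e-9:
                a /= n
        if abs(self.axis_u @ self.axis_v) > 1e-9:
            raise ValueError("plane axes must be orthonormal")

    @property
    def shape(self) -> tuple[int, int]:
        nu = max(1, int(round(self.extent[0] / self.pitch)))
        nv = max(1, int(round(self.extent[1] / self.pitch)))
        return nu, nv

    def pixel_centres(self) -> np.ndarray:
        """(nu, nv, 3) world positions of pixel centres."""
        nu, nv = self.shape
        iu = (np.arange(nu) + 0.5) * self.pitch
        iv = (np.arange(nv) + 0.5) * self.pitch
        return (
            self.origin
            + iu[:, None, None] * self.axis_u
            + iv[None, :, None] * self.axis_v
        )


@dataclass
class TetraEmbedding:
    """Coarse tetrahedral lattice skinned to the particle clusters."""

    rest_vertices: np.ndarray  # (n, 3) mm
    tets: np.ndarray  # (t, 4) int
    binding: SkinBinding

    def deformed_vertices(self, clusters) -> np.ndarray:
        return deform_points(self.binding, clusters)


def bind_skin(points: np.ndarray, clusters) -> SkinBinding:
    """Attach points to their four nearest cluster frames.

    Weights are proportional to 1/(d² + ε) with d the distance from the
    point to the cluster origin (the rest centre of mass), normalised to sum
    to one; a point sitting exactly on an origin is dominated by that frame.
    """
    if len(clusters) == 0:
        raise ValueError("at least one cluster required")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    origins = np.stack([c.origin for c in clusters])
    k = min(4, len(clusters))
    tree = cKDTree(origins)
    d, idx = tree.query(pts, k=k)
    d = d.reshape(len(pts), k)
    idx = idx.reshape(len(pts), k)
    w = 1.0 / (d**2 + _WEIGHT_EPS)
    w /= w.sum(axis=1, keepdims=True)
    offsets = pts[:, None, :] - origins[idx]
    return SkinBinding(cluster_indices=idx, weights=w, offsets=offsets)


def deform_points(binding: SkinBinding, clusters) -> np.ndarray:
    """World positions of skinned points under the current cluster states.

    p = Σ_k w_k (R_k · offset_k + com_k).  When every cluster carries the
    same rigid transform the result is that transform applied to the rest
    point (rigid reproduction).
    """
    R = np.stack([np.asarray(c.rotation) for c in clusters])
    com = np.stack([np.asarray(c.com) for c in clusters])
    Rk = R[binding.cluster_indices]  # (n, k, 3, 3)
    rotated = np.einsum("nkij,nkj->nki", Rk, binding.offsets)
    frames = rotated + com[binding.cluster_indices]
    return (binding.weights[:, :, None] * frames).sum(axis=1)


_CUBE_CORNERS = np.array(
    [[i & 1, (i >> 1) & 1, (i >> 2) & 1] for i in range(8)], dtype=float
)
# five-tetrahedron decomposition (central tet + four corner tets); the
# mirrored variant is used on odd-parity cells so faces conform across cells
_TETS_EVEN = np.array(
    [[1, 2, 4, 7], [0, 1, 2, 4], [3, 1, 7, 2], [5, 1, 4, 7], [6, 2, 7, 4]]
)
_TETS_ODD = _TETS_EVEN ^ 1  # flip the x bit of every corner index


def build_tet_lattice(
    mesh: TriangleMesh, spacing: float
) -> tuple[np.ndarray, np.ndarray]:
    """Regular cube lattice over the mesh, each cube split into 5 tetrahedra.

    Cells that cannot intersect the mesh (centre farther from the surface
    than the cell half-diagonal, on the outside) are discarded.  Returns
    (vertices, tets); the skinning of the vertices is the caller's job (see
    :func:`embed_mesh`).
    """
    lo, hi = mesh.bounds
    if spacing <= 0 or np.any(spacing > (hi - lo).max()):
        raise ValueError("invalid lattice spacing for this mesh")
    counts = np.maximum(1, np.ceil((hi - lo) / spacing - 1e-9).astype(int))
    nx, ny, nz = counts + 1
    grid = np.stack(
        np.meshgrid(
            lo[0] + spacing * np.arange(nx),
            lo[1] + spacing * np.arange(ny),
            lo[2] + spacing * np.arange(nz),
            indexing="ij",
        ),
        axis=-1,
    )
    vertices = grid.reshape(-1, 3)

    def vid(i, j, k):
        return (i * ny + j) * nz + k

    ci, cj, ck = np.meshgrid(
        np.arange(counts[0]), np.arange(counts[1]), np.arange(counts[2]),
        indexing="ij",
    )
    cells = np.stack([ci.ravel(), cj.ravel(), ck.ravel()], axis=1)
    centres = lo + (cells + 0.5) * spacing
    half_diag = 0.5 * np.sqrt(3.0) * spacing
    query = StaticMeshShape(mesh)
    d, _, _ = query.signed_distance(centres)
    keep = d <= half_diag
    cells = cells[keep]

    tets = []
    for i, j, k in cells:
        corner_ids = np.array(
            [
                vid(i + int(c[0]), j + int(c[1]), k + int(c[2]))
                for c in _CUBE_CORNERS
            ]
        )
        local = _TETS_EVEN if (i + j + k) % 2 == 0 else _TETS_ODD
        tets.extend(corner_ids[local])
    tets = np.asarray(tets, dtype=np.int64).reshape(-1, 4)

    # compact to used vertices, positively orient every tetrahedron
    used, inverse = np.unique(tets, return_inverse=True)
    tets = inverse.reshape(-1, 4)
    vertices = vertices[used]
    v = vertices[tets]
    vol6 = np.einsum(
        "ij,ij->i",
        np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]),
        v[:, 3] - v[:, 0],
    )
    flip = vol6 < 0
    tets[flip, 2], tets[flip, 3] = tets[flip, 3].copy(), tets[flip, 2].copy()
    return vertices, tets


def embed_mesh(mesh: TriangleMesh, clusters, spacing: float) -> TetraEmbedding:
    """Build and skin the tetra lattice for a mesh in one call."""
    vertices, tets = build_tet_lattice(mesh, spacing)
    return TetraEmbedding(
        rest_vertices=vertices, tets=tets, binding=bind_skin(vertices, clusters)
    )


def locate_barycentric(
    points: np.ndarray,
    vertices: np.ndarray,
    tets: np.ndarray,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Containing tetrahedron and barycentric coordinates of each point.

    Returns (tet_id, bary) with tet_id = −1 marking background points.
    Points on shared faces are assigned to the containing tetrahedron with
    the lowest id; barycentric coordinates sum to one and reconstruct the
    point exactly (up to round-off).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    vertices = np.asarray(vertices, dtype=float)
    tets = np.asarray(tets, dtype=np.int64)
    n = len(pts)
    tet_id = np.full(n, -1, dtype=np.int64)
    bary = np.zeros((n, 4))
    if len(tets) == 0:
        return tet_id, bary

    tv = vertices[tets]  # (t, 4, 3)
    centroids = tv.mean(axis=1)
    reach = np.linalg.norm(tv - centroids[:, None, :], axis=2).max()
    M = np.stack(
        [tv[:, 1] - tv[:, 0], tv[:, 2] - tv[:, 0], tv[:, 3] - tv[:, 0]], axis=2
    )
    Minv = np.linalg.inv(M)
    tree = cKDTree(centroids)
    groups = tree.query_ball_point(pts, reach * (1.0 + 1e-9))
    for k in range(n):
        cand = np.asarray(sorted(groups[k]), dtype=np.int64)
        if len(cand) == 0:
            continue
        rel = pts[k] - tv[cand, 0]
        b123 = np.einsum("tij,tj->ti", Minv[cand], rel)
        b0 = 1.0 - b123.sum(axis=1)
        full = np.column_stack([b0, b123])
        ok = np.flatnonzero((full >= -tol).all(axis=1))
        if len(ok):
            j = ok[0]  # candidates sorted: lowest tet id wins ties
            tet_id[k] = cand[j]
            bary[k] = full[j]
    return tet_id, bary


def save_slice_pgm(image: np.ndarray, path, plane: ScanPlane | None = None) -> None:
    """Export a resliced image as plain-text PGM plus a JSON pose sidecar.

    Intensities are min-max scaled to 0–255; the sidecar (``<path>.json``)
    records the plane origin, axes, extent and pixel pitch in mm.
    """
    import json
    from pathlib import Path

    path = Path(path)
    img = np.asarray(image, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    scale = 255.0 / (hi - lo) if hi > lo else 0.0
    pix = np.round((img - lo) * scale).astype(int)
    lines = [f"P2\n{img.shape[1]} {img.shape[0]}\n255"]
    lines += [" ".join(str(v) for v in row) for row in pix]
    path.write_text("\n".join(lines) + "\n")
    if plane is not None:
        sidecar = {
            "origin_mm": plane.origin.tolist(),
            "axis_u": plane.axis_u.tolist(),
            "axis_v": plane.axis_v.tolist(),
            "extent_mm": list(plane.extent),
            "pitch_mm": plane.pitch,
            "intensity_window": [lo, hi],
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def slice_ultrasound(
    plane: ScanPlane,
    embedding: TetraEmbedding,
    volume: VolumeImage,
    deformed_vertices: np.ndarray | None = None,
    background: float = 0.0,
    return_mask: bool = False,
):
    """Simulated 2D ultrasound image of the deforming volume.

    Each pixel centre is located in the deformed tetrahedra; its barycentric
    coordinates applied to the rest vertices give the corresponding point in
    the original acquisition frame, where the volume is sampled trilinearly.
    Pixels outside every tetrahedron receive the ``background`` sentinel.
    """
    if deformed_vertices is None:
        deformed_vertices = embedding.rest_vertices
    centres = plane.pixel_centres()
    nu, nv = centres.shape[:2]
    flat = centres.reshape(-1, 3)
    tet_id, bary = locate_barycentric(flat, deformed_vertices, embedding.tets)
    inside = tet_id >= 0
    image = np.full(nu * nv, float(background))
    if np.any(inside):
        rest_tv = embedding.rest_vertices[embedding.tets[tet_id[inside]]]
        rest_pts = (bary[inside, :, None] * rest_tv).sum(axis=1)
        image[inside] = volume.sample_trilinear(rest_pts, outside_value=background)
    image = image.reshape(nu, nv)
    if return_mask:
        return image, inside.reshape(nu, nv)
    return image
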