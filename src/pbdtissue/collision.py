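"""Contact generation and projection against static and kinematic shapes.

Three obstacle primitives are supported: infinite static planes, static
triangle meshes (the organ support), and kinematic convex shapes given as an
intersection of half-spaces (the ultrasound probe, a cuboid).  A particle of
radius r contacts a shape when its signed distance falls strictly below r;
the contact stores the outward normal and the penetration depth r − d, and
projection moves the particle back to exactly one radius from the surface
with a Coulomb-capped tangential (friction) correction.

The probe is kinematic: its pose is prescribed per step and contacts never
alter it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .io import TriangleMesh

__all__ = [
    "PlaneShape",
    "ConvexShape",
    "StaticMeshShape",
    "Contact",
    "detect_contacts",
    "project_contact",
    "particle_particle_contacts",
    "project_particle_pair",
]


@dataclass
class Contact:
    particle: int
    point: np.ndarray  # witness point on the obstacle surface, mm
    normal: np.ndarray  # unit, pointing away from the obstacle
    depth: float  # penetration incl. particle radius, > 0 when active
    friction: float = 0.0


class PlaneShape:
    """Static half-space obstacle: admissible side is normal · x ≥ offset."""

    def __init__(self, normal, offset: float, friction: float | None = None):
        n = np.asarray(normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("plane normal must be nonzero")
        self.normal = n / norm
        self.offset = float(offset) / norm
        self.friction = friction

    def signed_distance(self, points: np.ndarray, max_distance: float | None = None):
        pts = np.atleast_2d(points)
        d = pts @ self.normal - self.offset
        normals = np.broadcast_to(self.normal, pts.shape)
        witness = pts - d[:, None] * normals
        return d, normals.copy(), witness


class ConvexShape:
    """Kinematic convex obstacle as an intersection of half-spaces.

    Interior signed distance is the maximum of the half-space distances
    (exact).  Exterior distance is exact for shapes built with
    :meth:`box` (oriented-box closest point); for a generic half-space list
    the maximum-plane value is used, which is exact in face regions and a
    lower bound near edges.
    """

    def __init__(self, normals, offsets, friction: float | None = None):
        self.local_normals = np.asarray(normals, dtype=float).reshape(-1, 3)
        lengths = np.linalg.norm(self.local_normals, axis=1)
        if len(self.local_normals) == 0 or np.any(lengths == 0):
            raise ValueError("convex shape needs nonzero half-space normals")
        self.local_normals /= lengths[:, None]
        self.local_offsets = np.asarray(offsets, dtype=float).reshape(-1) / lengths
        self.friction = friction
        self._half_extents: np.ndarray | None = None
        self.rotation = np.eye(3)
        self.translation = np.zeros(3)

    @classmethod
    def box(cls, half_extents, friction: float | None = None) -> "ConvexShape":
        """Axis-aligned cuboid of the given half extents, pose at identity."""
        he = np.asarray(half_extents, dtype=float).reshape(3)
        normals = np.vstack([np.eye(3), -np.eye(3)])
        offsets = np.concatenate([he, he])
        shape = cls(normals, offsets, friction=friction)
        shape._half_extents = he
        return shape

    def set_pose(self, rotation=None, translation=None) -> None:
        if rotation is not None:
            self.rotation = np.asarray(rotation, dtype=float).reshape(3, 3)
        if translation is not None:
            self.translation = np.asarray(translation, dtype=float).reshape(3)

    def signed_distance(self, points: np.ndarray, max_distance: float | None = None):
        pts = np.atleast_2d(points)
        local = (pts - self.translation) @ self.rotation  # R^T (x - t)
        plane_d = local @ self.local_normals.T - self.local_offsets
        nearest = np.argmax(plane_d, axis=1)
        d = plane_d[np.arange(len(pts)), nearest]
        normals_local = self.local_normals[nearest]
        if self._half_extents is not None:
            outside = d > 0
            if np.any(outside):
                he = self._half_extents
                clamped = np.clip(local[outside], -he, he)
                diff = local[outside] - clamped
                dist = np.linalg.norm(diff, axis=1)
                d[outside] = dist
                nz = dist > 0
                n_out = normals_local[outside]
                n_out[nz] = diff[nz] / dist[nz, None]
                normals_local[outside] = n_out
        normals = normals_local @ self.rotation.T
        witness = pts - d[:, None] * normals
        return d, normals, witness


def _angle_weighted_vertex_normals(vertices, faces, face_normals):
    tri = vertices[faces]
    normals = np.zeros_like(vertices)
    for corner in range(3):
        a = tri[:, corner]
        b = tri[:, (corner + 1) % 3]
        c = tri[:, (corner + 2) % 3]
        u = b - a
        v = c - a
        cosang = np.einsum("ij,ij->i", u, v) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1) + 1e-300
        )
        ang = np.arccos(np.clip(cosang, -1.0, 1.0))
        np.add.at(normals, faces[:, corner], ang[:, None] * face_normals)
    lengths = np.linalg.norm(normals, axis=1)
    lengths[lengths == 0] = 1.0
    return normals / lengths[:, None]


class StaticMeshShape:
    """Static triangle-mesh obstacle with pseudonormal signed distance.

    The nearest triangle is found via a centroid KD-tree prefilter; the sign
    of the distance comes from the angle-weighted pseudonormal of the closest
    feature (face, edge or vertex), which is robust for closed meshes.
    Intended for closed support geometry (a thick concave slab here).
    """

    def __init__(self, mesh: TriangleMesh, friction: float | None = None):
        self.mesh = mesh
        self.friction = friction
        tm = mesh.to_trimesh()
        self.triangles = mesh.vertices[mesh.faces]  # (m, 3, 3)
        self.face_normals = np.asarray(tm.face_normals, dtype=float)
        self.vertex_normals = _angle_weighted_vertex_normals(
            mesh.vertices, mesh.faces, self.face_normals
        )
        # edge pseudonormals: mean of adjacent face normals
        edges = {}
        for f, face in enumerate(mesh.faces):
            for e in ((0, 1), (1, 2), (2, 0)):
                key = tuple(sorted((face[e[0]], face[e[1]])))
                edges.setdefault(key, []).append(f)
        self.edge_normals = {}
        for key, fs in edges.items():
            n = self.face_normals[fs].sum(axis=0)
            norm = np.linalg.norm(n)
            self.edge_normals[key] = n / norm if norm > 0 else self.face_normals[fs[0]]
        # per-face slot s holds the pseudonormal of the edge opposite vertex s
        self.edge_normals_by_slot = np.empty((len(mesh.faces), 3, 3))
        for f, face in enumerate(mesh.faces):
            for s in range(3):
                a, b = face[(s + 1) % 3], face[(s + 2) % 3]
                self.edge_normals_by_slot[f, s] = self.edge_normals[
                    tuple(sorted((int(a), int(b))))
                ]
        self._centroids = self.triangles.mean(axis=1)
        self._tree = cKDTree(self._centroids)
        self._tri_radius = np.linalg.norm(
            self.triangles - self._centroids[:, None, :], axis=2
        ).max(axis=1)
        self._max_tri_radius = float(self._tri_radius.max())
        self._cell_pad: float | None = None

    def _ensure_cell_index(self, pad: float) -> None:
        """Voxel hash: cell id → triangles whose padded AABB overlaps the cell.

        A point in a cell is guaranteed to see every triangle within ``pad``
        of it among that cell's triangles; points outside the padded grid are
        farther than ``pad`` from the whole mesh.
        """
        if self._cell_pad is not None and pad <= self._cell_pad:
            return
        self._cell_pad = pad
        tmin = self.triangles.min(axis=1) - pad
        tmax = self.triangles.max(axis=1) + pad
        h = max(pad, 2.0 * float(np.median(self._tri_radius)), 1e-6)
        lo = tmin.min(axis=0)
        self._cell_h = h
        self._cell_lo = lo
        i0 = np.floor((tmin - lo) / h).astype(np.int64)
        i1 = np.floor((tmax - lo) / h).astype(np.int64)
        dims = i1.max(axis=0) + 1
        self._cell_dims = dims
        cell_of: dict[int, list[int]] = {}
        for t in range(len(self.triangles)):
            for ix in range(i0[t, 0], i1[t, 0] + 1):
                for iy in range(i0[t, 1], i1[t, 1] + 1):
                    for iz in range(i0[t, 2], i1[t, 2] + 1):
                        key = (ix * dims[1] + iy) * dims[2] + iz
                        cell_of.setdefault(key, []).append(t)
        keys = np.array(sorted(cell_of), dtype=np.int64)
        lengths = np.array([len(cell_of[k]) for k in keys], dtype=np.int64)
        self._cell_keys = keys
        self._cell_offsets = np.concatenate([[0], np.cumsum(lengths)])
        self._cell_tris = np.concatenate(
            [np.asarray(cell_of[k], dtype=np.int64) for k in keys]
        )

    def candidate_pairs(self, points: np.ndarray, max_distance: float):
        """(point, triangle) pairs that can be within max_distance of each other.

        Used to cache the relevant triangles for a set of particles over a
        solver substep, so per-iteration re-projection skips the spatial query.
        """
        self._ensure_cell_index(max_distance)
        pts = np.atleast_2d(points)
        cell = np.floor((pts - self._cell_lo) / self._cell_h).astype(np.int64)
        dims = self._cell_dims
        in_grid = np.all((cell >= 0) & (cell < dims), axis=1)
        keys = (cell[:, 0] * dims[1] + cell[:, 1]) * dims[2] + cell[:, 2]
        pos = np.searchsorted(self._cell_keys, keys)
        pos_c = np.minimum(pos, len(self._cell_keys) - 1)
        hit = in_grid & (self._cell_keys[pos_c] == keys)
        if not np.any(hit):
            return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
        which = np.flatnonzero(hit)
        starts = self._cell_offsets[pos_c[which]]
        lengths = self._cell_offsets[pos_c[which] + 1] - starts
        total = int(lengths.sum())
        pt_idx = np.repeat(which, lengths)
        base = np.repeat(starts - np.concatenate([[0], np.cumsum(lengths)[:-1]]), lengths)
        tri_idx = self._cell_tris[base + np.arange(total)]
        # per-triangle refinement of the conservative cell bound
        diff = pts[pt_idx] - self._centroids[tri_idx]
        reach = max_distance + self._tri_radius[tri_idx]
        keep = np.einsum("ij,ij->i", diff, diff) <= reach * reach
        return pt_idx[keep], tri_idx[keep]

    def signed_distance_from_pairs(
        self,
        points: np.ndarray,
        pt_idx: np.ndarray,
        tri_idx: np.ndarray,
        return_pair_distance: bool = False,
    ):
        """Signed distance/normal/witness from precomputed candidate pairs.

        Points without any candidate pair are reported at +inf distance.
        With ``return_pair_distance`` the per-pair unsigned distances are
        appended to the result (used to prune cached pairs).
        """
        pts = np.atleast_2d(points)
        n_pts = len(pts)
        dist = np.full(n_pts, np.inf)
        closest = pts.copy()
        tri_of = np.full(n_pts, -1, dtype=np.int64)
        bary_of = np.zeros((n_pts, 3))
        d2 = np.zeros(0)
        if len(pt_idx):
            cp, bc = _closest_point_triangles(pts[pt_idx], self.triangles[tri_idx])
            d2 = ((pts[pt_idx] - cp) ** 2).sum(axis=1)
            order = np.lexsort((d2, pt_idx))
            first = np.ones(len(order), dtype=bool)
            pi_sorted = pt_idx[order]
            first[1:] = pi_sorted[1:] != pi_sorted[:-1]
            sel = order[first]
            upd = pt_idx[sel]
            dist[upd] = np.sqrt(d2[sel])
            closest[upd] = cp[sel]
            tri_of[upd] = tri_idx[sel]
            bary_of[upd] = bc[sel]
        result = self._finish_signed(pts, dist, closest, tri_of, bary_of)
        if return_pair_distance:
            return (*result, np.sqrt(d2))
        return result

    def signed_distance(self, points: np.ndarray, max_distance: float | None = None):
        """Signed distances, outward normals and witness points.

        With ``max_distance`` given, points farther than that from the surface
        are reported as +inf distance (cheap culling for contact queries).
        """
        pts = np.atleast_2d(points)
        n_pts = len(pts)
        if max_distance is not None:
            pt_idx, tri_idx = self.candidate_pairs(pts, max_distance)
            return self.signed_distance_from_pairs(pts, pt_idx, tri_idx)
        dist = np.full(n_pts, np.inf)
        closest = pts.copy()
        tri_of = np.full(n_pts, -1, dtype=np.int64)
        bary_of = np.zeros((n_pts, 3))
        r_query = 2.0 * self._max_tri_radius + 1.0
        remaining = np.arange(n_pts)
        while len(remaining):
            groups = self._tree.query_ball_point(pts[remaining], r_query)
            counts = np.array([len(g) for g in groups])
            has = counts > 0
            if np.any(has):
                pt_idx = np.repeat(remaining[has], counts[has])
                tri_idx = np.concatenate(
                    [np.asarray(g, dtype=np.int64) for g in groups if g]
                )
                cp, bc = _closest_point_triangles(
                    pts[pt_idx], self.triangles[tri_idx]
                )
                d2 = ((pts[pt_idx] - cp) ** 2).sum(axis=1)
                order = np.lexsort((d2, pt_idx))
                first = np.ones(len(order), dtype=bool)
                pi_sorted = pt_idx[order]
                first[1:] = pi_sorted[1:] != pi_sorted[:-1]
                sel = order[first]
                d_best = np.sqrt(d2[sel])
                # exact only if no triangle outside the ball can be closer
                exact = d_best <= r_query - self._max_tri_radius
                upd = pt_idx[sel][exact]
                dist[upd] = d_best[exact]
                closest[upd] = cp[sel][exact]
                tri_of[upd] = tri_idx[sel][exact]
                bary_of[upd] = bc[sel][exact]
            remaining = np.setdiff1d(
                remaining, np.flatnonzero(np.isfinite(dist)), assume_unique=False
            )
            r_query *= 2.0
            if r_query > 1e9:  # pragma: no cover - degenerate mesh guard
                break
        return self._finish_signed(pts, dist, closest, tri_of, bary_of)

    def _finish_signed(self, pts, dist, closest, tri_of, bary_of):
        n_pts = len(pts)
        found = tri_of >= 0
        normals = np.zeros((n_pts, 3))
        normals[:, 2] = 1.0
        signs = np.ones(n_pts)
        if np.any(found):
            pn = self._pseudonormals(tri_of[found], bary_of[found])
            diff = pts[found] - closest[found]
            d = dist[found]
            far = d > 1e-9
            direction = np.zeros_like(diff)
            direction[far] = diff[far] / d[far, None]
            inward = far & (np.einsum("ij,ij->i", direction, pn) < 0)
            nrm = np.where(
                (far & ~inward)[:, None], direction, pn
            )  # inside or on-surface: push out along the pseudonormal
            normals[found] = nrm
            s = np.ones(len(d))
            s[inward] = -1.0
            signs[found] = s
        return signs * dist, normals, closest

    def _pseudonormals(self, tri: np.ndarray, bary: np.ndarray) -> np.ndarray:
        """Angle-weighted pseudonormal of the closest feature, vectorised."""
        eps = 1e-9
        zero = bary < eps
        n_zero = zero.sum(axis=1)
        pn = self.face_normals[tri].copy()
        edge_case = n_zero == 1
        if np.any(edge_case):
            slot = np.argmax(zero[edge_case], axis=1)
            pn[edge_case] = self.edge_normals_by_slot[tri[edge_case], slot]
        vert_case = n_zero >= 2
        if np.any(vert_case):
            slot = np.argmax(~zero[vert_case], axis=1)
            vid = self.mesh.faces[tri[vert_case], slot]
            pn[vert_case] = self.vertex_normals[vid]
        return pn


def _closest_point_triangles(p: np.ndarray, tri: np.ndarray):
    """Closest points of p on each triangle (Ericson's algorithm, vectorised).

    Returns the closest points (m, 3) and their barycentric coordinates
    (m, 3) w.r.t. vertices (a, b, c).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp_ = p - c
    d5 = np.einsum("ij,ij->i", ab, cp_)
    d6 = np.einsum("ij,ij->i", ac, cp_)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    m = len(tri)
    out = np.empty((m, 3))
    bary = np.empty((m, 3))
    done = np.zeros(m, dtype=bool)

    def assign(mask, pts, bc):
        todo = mask & ~done
        out[todo] = pts[todo] if pts.ndim == 2 else pts
        bary[todo] = bc[todo] if bc.ndim == 2 else bc
        done[todo] = True

    assign((d1 <= 0) & (d2 <= 0), a, np.broadcast_to([1.0, 0, 0], (m, 3)))
    assign((d3 >= 0) & (d4 <= d3), b, np.broadcast_to([0, 1.0, 0], (m, 3)))
    assign((d6 >= 0) & (d5 <= d6), c, np.broadcast_to([0, 0, 1.0], (m, 3)))

    v_ab = d1 / np.where(d1 - d3 == 0, 1.0, d1 - d3)
    mask_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    bc_ab = np.stack([1 - v_ab, v_ab, np.zeros(m)], axis=1)
    assign(mask_ab, a + v_ab[:, None] * ab, bc_ab)

    w_ac = d2 / np.where(d2 - d6 == 0, 1.0, d2 - d6)
    mask_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    bc_ac = np.stack([1 - w_ac, np.zeros(m), w_ac], axis=1)
    assign(mask_ac, a + w_ac[:, None] * ac, bc_ac)

    denom_bc = (d4 - d3) + (d5 - d6)
    w_bc = (d4 - d3) / np.where(denom_bc == 0, 1.0, denom_bc)
    mask_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    bc_bc = np.stack([np.zeros(m), 1 - w_bc, w_bc], axis=1)
    assign(mask_bc, b + w_bc[:, None] * (c - b), bc_bc)

    denom = va + vb + vc
    denom = np.where(denom == 0, 1.0, denom)
    v = vb / denom
    w = vc / denom
    bc_face = np.stack([1 - v - w, v, w], axis=1)
    assign(np.ones(m, dtype=bool), a + v[:, None] * ab + w[:, None] * ac, bc_face)
    return out, bary


def detect_contacts(
    positions: np.ndarray,
    radius: float,
    shapes,
    default_friction: float = 0.0,
    margin: float = 0.0,
) -> list[Contact]:
    """One contact per (particle, shape) pair with signed distance < radius.

    ``margin`` widens detection (used when caching contacts for a substep so
    that projection in later iterations still sees relevant pairs).
    """
    pts = np.atleast_2d(positions)
    contacts: list[Contact] = []
    for shape in shapes:
        d, n, w = shape.signed_distance(pts)
        friction = shape.friction if shape.friction is not None else default_friction
        for i in np.flatnonzero(d < radius + margin):
            contacts.append(
                Contact(
                    particle=int(i),
                    point=w[i],
                    normal=n[i],
                    depth=float(radius - d[i]),
                    friction=friction,
                )
            )
    return contacts


def project_contact(
    contact: Contact,
    x: np.ndarray,
    inverse_masses: np.ndarray,
    tangential_motion: np.ndarray | None = None,
) -> np.ndarray:
    """Per-particle displacement resolving one particle-vs-obstacle contact.

    Normal part pushes the particle to exactly one radius from the surface;
    the tangential part opposes ``tangential_motion`` (the particle's slide
    during this substep) with magnitude capped at μ·|Δx_n| (Coulomb).
    Obstacles are static or kinematic, so only the particle moves.
    """
    delta = np.zeros_like(np.atleast_2d(x), dtype=float)
    i = contact.particle
    if inverse_masses[i] == 0 or contact.depth <= 0:
        return delta
    dx_n = contact.depth * contact.normal
    delta[i] = dx_n
    if tangential_motion is not None and contact.friction > 0:
        u = np.asarray(tangential_motion, dtype=float)
        u_t = u - (u @ contact.normal) * contact.normal
        slide = np.linalg.norm(u_t)
        if slide > 1e-12:
            cap = contact.friction * np.linalg.norm(dx_n)
            delta[i] -= min(slide, cap) * (u_t / slide)
    return delta


def particle_particle_contacts(
    positions: np.ndarray, radius: float, friction: float = 0.0
) -> list[tuple[int, int]]:
    """Index pairs of particles strictly closer than 2·radius."""
    pts = np.atleast_2d(positions)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(2.0 * radius, output_type="ndarray")
    if len(pairs) == 0:
        return []
    d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
    keep = d < 2.0 * radius  # strict inequality convention
    return [tuple(p) for p in pairs[keep]]


def project_particle_pair(
    i: int,
    j: int,
    x: np.ndarray,
    inverse_masses: np.ndarray,
    radius: float,
) -> np.ndarray:
    """Displacements separating one overlapping particle pair.

    The overlap is removed along the pair axis, split by inverse mass
    (heavier particles move less; infinite-mass particles not at all).
    """
    delta = np.zeros_like(np.atleast_2d(x), dtype=float)
    diff = x[i] - x[j]
    dist = np.linalg.norm(diff)
    if dist >= 2.0 * radius or dist == 0:
        return delta
    n = diff / dist
    overlap = 2.0 * radius - dist
    w_sum = inverse_masses[i] + inverse_masses[j]
    if w_sum == 0:
        return delta
    delta[i] = (inverse_masses[i] / w_sum) * overlap * n
    delta[j] = -(inverse_masses[j] / w_sum) * overlap * n
    return delta
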