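"""Position-based dynamics time stepping with averaged (Jacobi) projection.

One time step performs, per substep: a symplectic-Euler prediction under
gravity, one contact-detection pass (contacts are cached for the substep),
a fixed number of constraint-projection iterations, and a velocity update
from the net position change followed by exponential damping.

Within an iteration every constraint is evaluated against the same positions
and the per-particle displacement contributions are accumulated together with
the number of constraints touching each particle; the accumulated
displacement is then applied scaled by factor/nᵢ ("local" relaxation,
factor 1 by default) or w/nᵢ with the successive over-relaxation weight
w ∈ [1, 2] ("global" mode).  Constraints are processed in precedence groups:
contacts first, then the shape-matching clusters, so that stiffness updates
never re-embed particles in obstacles.

The cluster stiffness α is applied per iteration without iteration-count
compensation, so the realised material stiffness depends on the iteration
and substep counts; α must be calibrated in the context of those settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .collision import (
    ConvexShape,
    detect_contacts,
    particle_particle_contacts,
)
from .io import SimulationConfig
from .sampling import Cluster, ParticleSet
from .shape_matching import optimal_rotation_batch

__all__ = [
    "Constraint",
    "DistanceConstraint",
    "SolverState",
    "predict",
    "project_constraint",
    "iterate",
    "finalize",
    "Scene",
    "Simulator",
]


class Constraint:
    """A scalar constraint C(x) with gradient, projected via its multiplier.

    ``kind`` is "equality" (project always) or "inequality" (project only
    when C < 0).  ``group`` is the precedence tier: lower groups are
    projected and applied before higher ones within each iteration.
    """

    kind: str = "equality"
    group: int = 0
    particles: np.ndarray

    def evaluate(self, x: np.ndarray) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def gradient(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class DistanceConstraint(Constraint):
    """C(x) = |x_i - x_j| - rest_length (equality)."""

    def __init__(self, i: int, j: int, rest_length: float, kind: str = "equality"):
        self.particles = np.array([i, j], dtype=np.int64)
        self.rest_length = float(rest_length)
        self.kind = kind

    def evaluate(self, x: np.ndarray) -> float:
        i, j = self.particles
        return float(np.linalg.norm(x[i] - x[j]) - self.rest_length)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        i, j = self.particles
        diff = x[i] - x[j]
        dist = np.linalg.norm(diff)
        if dist < 1e-12:
            return np.zeros((2, 3))
        n = diff / dist
        return np.stack([n, -n])


@dataclass
class SolverState:
    """Mutable particle state: positions (mm), velocities (mm/s), 1/mass (1/g).

    An inverse mass of zero marks a fixed particle: it is never displaced by
    prediction or projection.
    """

    x: np.ndarray
    v: np.ndarray
    inverse_masses: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).reshape(-1, 3)
        self.v = np.asarray(self.v, dtype=float).reshape(-1, 3)
        self.inverse_masses = np.asarray(self.inverse_masses, dtype=float).reshape(-1)

    @property
    def movable(self) -> np.ndarray:
        return self.inverse_masses > 0


def predict(state: SolverState, dt: float, gravity=(0.0, 0.0, 0.0)):
    """Symplectic-Euler prediction: v* = v + dt·g, x* = x + dt·v*.

    Fixed particles keep their position and velocity.  Returns (x*, v*)
    without mutating the state.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    g = np.asarray(gravity, dtype=float).reshape(3)
    movable = state.movable[:, None]
    v_star = state.v + dt * g * movable
    x_star = state.x + dt * v_star * movable
    return x_star, v_star


def project_constraint(c: Constraint, x: np.ndarray, inverse_masses: np.ndarray):
    """Single-constraint projection: multiplier and per-particle displacement.

    λ = −C / (∇C M⁻¹ ∇Cᵀ) and Δx = M⁻¹ ∇Cᵀ λ, restricted to the touched
    particles.  Satisfied inequalities and zero-gradient or all-fixed
    constraints return λ = 0 and no displacement (the constraint is skipped
    for this iteration rather than raising).
    """
    value = c.evaluate(x)
    delta = np.zeros((len(c.particles), 3))
    if c.kind == "inequality" and value >= 0:
        return 0.0, delta
    grad = c.gradient(x)
    w = inverse_masses[c.particles]
    denom = float((w[:, None] * grad * grad).sum())
    if denom <= 1e-300:
        return 0.0, delta
    lam = -value / denom
    delta = w[:, None] * grad * lam
    return lam, delta


def iterate(
    x: np.ndarray,
    constraints,
    inverse_masses: np.ndarray,
    iterations: int,
    relaxation_mode: str = "local",
    relaxation_factor: float = 1.0,
) -> np.ndarray:
    """Jacobi-averaged constraint iterations over generic constraints.

    Per iteration and per precedence group, every constraint is projected
    against the same positions; accumulated per-particle displacements are
    applied scaled by factor/nᵢ where nᵢ counts the active constraints
    touching particle i.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    x = np.array(x, dtype=float)
    factor = relaxation_factor
    groups = sorted({c.group for c in constraints})
    for _ in range(iterations):
        for g in groups:
            delta = np.zeros_like(x)
            counts = np.zeros(len(x))
            for c in constraints:
                if c.group != g:
                    continue
                lam, d = project_constraint(c, x, inverse_masses)
                if lam == 0.0 and not np.any(d):
                    continue
                delta[c.particles] += d
                counts[c.particles] += 1
            active = counts > 0
            x[active] += factor * delta[active] / counts[active, None]
    return x


def finalize(
    state: SolverState,
    x_projected: np.ndarray,
    dt: float,
    damping_factor: float = 0.0,
) -> SolverState:
    """Velocity recovery v = Δx/dt, exponential damping, position commit.

    Damping multiplies velocities by max(0, 1 − k·dt), which is stable for
    any dt (the factor is clamped at total rest).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    movable = state.movable
    v = np.where(
        movable[:, None], (x_projected - state.x) / dt, state.v
    )
    scale = max(0.0, 1.0 - damping_factor * dt)
    v[movable] *= scale
    state.v = v
    state.x = np.where(movable[:, None], x_projected, state.x)
    return state


def _aabb_prefilter(shape, x: np.ndarray, reach: float) -> np.ndarray:
    """Indices of points within ``reach`` of the shape's bounding box.

    Planes and generic half-space shapes are unbounded and return all points.
    """
    lo = hi = None
    if hasattr(shape, "mesh"):  # static triangle mesh
        lo, hi = shape.mesh.bounds
    elif getattr(shape, "_half_extents", None) is not None:  # oriented box
        extent = np.abs(shape.rotation) @ shape._half_extents
        lo = shape.translation - extent
        hi = shape.translation + extent
    if lo is None:
        return np.arange(len(x))
    inside = np.all((x >= lo - reach) & (x <= hi + reach), axis=1)
    return np.flatnonzero(inside)


@dataclass
class Scene:
    """A simulation scene: particles, clusters and collision geometry.

    ``shapes`` are the static obstacles (support mesh, floor plane); the
    ``probe`` is kinematic — its pose is prescribed per step and contacts
    never alter it.
    """

    particles: ParticleSet
    clusters: list
    shapes: list = field(default_factory=list)
    probe: ConvexShape | None = None
    fixed: np.ndarray | None = None

    def all_shapes(self) -> list:
        return list(self.shapes) + ([self.probe] if self.probe is not None else [])


class Simulator:
    """Advances a :class:`Scene` in time under a :class:`SimulationConfig`.

    Shape-matching clusters act as a constraint group: each iteration every
    cluster computes its best-fit rigid transform of the rest shape onto the
    working positions and contributes Δxᵢ = α (gᵢ − xᵢ) to each member, which
    is averaged through the same accumulation machinery as the contacts.
    """

    def __init__(
        self,
        scene: Scene,
        config: SimulationConfig,
        alpha: float | None = None,
    ):
        self.scene = scene
        self.config = config
        self.alpha = config.alpha if alpha is None else float(alpha)
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")

        particles = scene.particles
        n = len(particles)
        masses = (
            particles.masses if particles.masses is not None else np.ones(n)
        )
        inv = 1.0 / masses
        if scene.fixed is not None:
            inv = np.where(scene.fixed, 0.0, inv)
        self.state = SolverState(
            x=particles.positions.copy(), v=np.zeros((n, 3)), inverse_masses=inv
        )
        self.masses = masses
        self.radius = particles.radius
        self._build_cluster_arrays(scene.clusters, masses)
        self.steps_taken = 0
        self.diagnostics: list[dict] = []

    # -- cluster bookkeeping -------------------------------------------------
    def _build_cluster_arrays(self, clusters: list, masses: np.ndarray) -> None:
        self.n_clusters = len(clusters)
        if self.n_clusters == 0:
            self.flat_c = np.zeros(0, dtype=np.int64)
            self.flat_p = np.zeros(0, dtype=np.int64)
            return
        self.flat_c = np.concatenate(
            [np.full(len(c), k, dtype=np.int64) for k, c in enumerate(clusters)]
        )
        self.flat_p = np.concatenate([c.member_indices for c in clusters])
        self.flat_m = masses[self.flat_p]
        # flat arrays are sorted by cluster by construction; clusters are
        # non-empty, so segment sums reduce over these start offsets
        self._seg_starts = np.concatenate(
            [[0], 1 + np.flatnonzero(np.diff(self.flat_c))]
        )
        rest = self.scene.particles.positions
        com_num = np.column_stack(
            [
                np.add.reduceat(self.flat_m * rest[self.flat_p, k], self._seg_starts)
                for k in range(3)
            ]
        )
        self.cluster_mass = np.add.reduceat(self.flat_m, self._seg_starts)
        self.rest_com = com_num / self.cluster_mass[:, None]
        self.flat_q = rest[self.flat_p] - self.rest_com[self.flat_c]
        self.flat_mq = self.flat_m[:, None] * self.flat_q
        self.membership_count = np.bincount(
            self.flat_p, minlength=len(rest)
        ).astype(float)
        # dividing each particle's cluster correction by its own membership
        # count (plain Eq-(7)-style averaging) would break the per-cluster
        # momentum balance wherever counts differ across a cluster; instead
        # every cluster's whole contribution is scaled by the maximum
        # membership count among its members, which conserves momentum per
        # cluster and never relaxes less than the per-particle rule
        cmax = np.zeros(self.n_clusters)
        np.maximum.at(cmax, self.flat_c, self.membership_count[self.flat_p])
        self.cluster_scale = 1.0 / cmax
        # clusters whose rest geometry is rank-deficient (fewer than three
        # non-collinear members) always need the warm-start regularisation
        self._degenerate = np.zeros(self.n_clusters, dtype=bool)
        for k, start in enumerate(self._seg_starts):
            end = (
                self._seg_starts[k + 1]
                if k + 1 < len(self._seg_starts)
                else len(self.flat_q)
            )
            q = self.flat_q[start:end]
            if len(q) < 3:
                self._degenerate[k] = True
            else:
                s = np.linalg.svd(q, compute_uv=False)
                if s[1] <= 1e-9 * max(s[0], 1e-300):
                    self._degenerate[k] = True
        self.rotations = np.broadcast_to(
            np.eye(3), (self.n_clusters, 3, 3)
        ).copy()
        self.cluster_com = self.rest_com.copy()

    def _cluster_pass(self, x: np.ndarray):
        """Goal displacements Δxᵢ = α Σ_c (g_i^c − xᵢ) with membership counts."""
        if self.n_clusters == 0:
            return np.zeros_like(x), np.zeros(len(x))
        xf = x[self.flat_p]
        mxf = self.flat_m[:, None] * xf
        com = np.add.reduceat(mxf, self._seg_starts, axis=0)
        com /= self.cluster_mass[:, None]
        p = xf - com[self.flat_c]
        outer = (p[:, :, None] * self.flat_mq[:, None, :]).reshape(-1, 9)
        A = np.add.reduceat(outer, self._seg_starts, axis=0).reshape(-1, 3, 3)
        R = optimal_rotation_batch(
            A, previous=self.rotations, known_degenerate=self._degenerate
        )
        self.rotations = R
        self.cluster_com = com
        goals = np.einsum("eij,ej->ei", R[self.flat_c], self.flat_q) + com[self.flat_c]
        contrib = (
            self.alpha * self.cluster_scale[self.flat_c, None] * (goals - xf)
        )
        delta = np.column_stack(
            [
                np.bincount(self.flat_p, weights=contrib[:, k], minlength=len(x))
                for k in range(3)
            ]
        )
        return delta, self.membership_count

    def sync_clusters(self) -> None:
        """Copy the stacked rigid state back into the Cluster objects."""
        for k, c in enumerate(self.scene.clusters):
            c.rotation = self.rotations[k].copy()
            c.com = self.cluster_com[k].copy()

    # -- contacts ------------------------------------------------------------
    def _detect_substep_contacts(self, x: np.ndarray):
        """Cache likely contacts for the substep: shape pairs + particle pairs.

        The detection margin keeps pairs that may activate as positions move
        during the iteration loop; static-mesh shapes additionally cache their
        candidate triangles so re-projection skips the spatial query.
        """
        margin = 0.5 * self.radius
        reach = self.radius + 2.0 * margin
        shape_cache = []
        for shape in self.scene.all_shapes():
            friction = (
                shape.friction
                if shape.friction is not None
                else self.config.shape_friction
            )
            near = _aabb_prefilter(shape, x, reach)
            if len(near) == 0:
                continue
            if hasattr(shape, "candidate_pairs"):
                pt_idx, tri_idx = shape.candidate_pairs(x[near], reach)
                if len(pt_idx) == 0:
                    continue
                # keep particles within the detection margin, and for those
                # only the triangles that can matter during this substep
                d, _, _, d_pair = shape.signed_distance_from_pairs(
                    x[near], pt_idx, tri_idx, return_pair_distance=True
                )
                local = np.flatnonzero(d < self.radius + margin)
                keep = np.isin(pt_idx, local) & (
                    d_pair < self.radius + 2.0 * margin
                )
                pt_idx, tri_idx = pt_idx[keep], tri_idx[keep]
                if len(pt_idx) == 0:
                    continue
                idx = near[local]
                remap_local = np.zeros(int(local.max()) + 1, dtype=np.int64)
                remap_local[local] = np.arange(len(local))
                shape_cache.append(
                    (shape, idx, friction, (remap_local[pt_idx], tri_idx))
                )
            else:
                d, _, _ = shape.signed_distance(x[near], max_distance=reach)
                idx = near[np.flatnonzero(d < self.radius + margin)]
                if len(idx):
                    shape_cache.append((shape, idx, friction, None))
        pairs = particle_particle_contacts(x, self.radius)
        pair_arr = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
        return shape_cache, pair_arr

    def _contact_pass(self, x: np.ndarray, x_substep_start: np.ndarray, cache):
        shape_cache, pair_arr = cache
        delta = np.zeros_like(x)
        counts = np.zeros(len(x))
        inv = self.state.inverse_masses
        for shape, idx, friction, pairs in shape_cache:
            if pairs is not None:
                d, n, _ = shape.signed_distance_from_pairs(x[idx], *pairs)
            else:
                d, n, _ = shape.signed_distance(
                    x[idx], max_distance=2.0 * self.radius
                )
            active = d < self.radius
            if not np.any(active):
                continue
            ia = idx[active]
            movable = inv[ia] > 0
            ia = ia[movable]
            if len(ia) == 0:
                continue
            na = n[active][movable]
            depth = (self.radius - d[active][movable])[:, None]
            dx = depth * na
            if friction > 0:
                u = x[ia] - x_substep_start[ia]
                u_t = u - np.einsum("ij,ij->i", u, na)[:, None] * na
                slide = np.linalg.norm(u_t, axis=1)
                cap = friction * np.abs(depth[:, 0])
                mag = np.minimum(slide, cap)
                nz = slide > 1e-12
                dx[nz] -= (mag[nz] / slide[nz])[:, None] * u_t[nz]
            np.add.at(delta, ia, dx)
            np.add.at(counts, ia, 1.0)
        pair_delta = np.zeros_like(x)
        if len(pair_arr):
            i, j = pair_arr[:, 0], pair_arr[:, 1]
            diff = x[i] - x[j]
            dist = np.linalg.norm(diff, axis=1)
            active = (dist < 2.0 * self.radius) & (dist > 0)
            if np.any(active):
                i, j = i[active], j[active]
                nvec = diff[active] / dist[active][:, None]
                overlap = (2.0 * self.radius - dist[active])[:, None]
                w_sum = inv[i] + inv[j]
                ok = w_sum > 0
                i, j, nvec, overlap, w_sum = (
                    i[ok],
                    j[ok],
                    nvec[ok],
                    overlap[ok],
                    w_sum[ok],
                )
                # averaging by each particle's own contact count would break
                # the pair's momentum balance (different counts on the two
                # sides); both partners are therefore normalised by the pair's
                # shared count max(n_i, n_j), which conserves momentum exactly
                # and under-relaxes at least as much as the per-particle rule
                n_pair = np.maximum(
                    np.bincount(i, minlength=len(x))[i]
                    + np.bincount(j, minlength=len(x))[i],
                    np.bincount(i, minlength=len(x))[j]
                    + np.bincount(j, minlength=len(x))[j],
                ).astype(float)
                scale = 1.0 / n_pair[:, None]
                np.add.at(
                    pair_delta, i, scale * (inv[i] / w_sum)[:, None] * overlap * nvec
                )
                np.add.at(
                    pair_delta, j, -scale * (inv[j] / w_sum)[:, None] * overlap * nvec
                )
        return delta, counts, pair_delta

    def _cancel_normal_velocity(self, cache) -> None:
        """Inelastic contact velocity pass: remove approaching normal velocity.

        Applied after the velocity recovery of each substep for every still
        active contact; prevents projection-induced jitter in resting piles
        (zero restitution).
        """
        shape_cache, pair_arr = cache
        x = self.state.x
        v = self.state.v
        inv = self.state.inverse_masses
        touch = self.radius * 1.02
        for shape, idx, _friction, pairs in shape_cache:
            if pairs is not None:
                d, n, _ = shape.signed_distance_from_pairs(x[idx], *pairs)
            else:
                d, n, _ = shape.signed_distance(
                    x[idx], max_distance=2.0 * self.radius
                )
            act = (d < touch) & (inv[idx] > 0)
            if not np.any(act):
                continue
            ia = idx[act]
            na = n[act]
            vn = np.einsum("ij,ij->i", v[ia], na)
            v[ia] -= vn[:, None] * na
        if len(pair_arr):
            i, j = pair_arr[:, 0], pair_arr[:, 1]
            diff = x[i] - x[j]
            dist = np.linalg.norm(diff, axis=1)
            act = (dist < 2.0 * touch) & (dist > 0)
            act &= (inv[i] + inv[j]) > 0
            if np.any(act):
                i, j = i[act], j[act]
                n = diff[act] / dist[act][:, None]
                vn_rel = np.einsum("ij,ij->i", v[i] - v[j], n)
                w_sum = inv[i] + inv[j]
                np.add.at(v, i, -((inv[i] / w_sum) * vn_rel)[:, None] * n)
                np.add.at(v, j, ((inv[j] / w_sum) * vn_rel)[:, None] * n)

    # -- stepping ------------------------------------------------------------
    def step(self) -> None:
        """Advance the scene by one full time step (all substeps)."""
        cfg = self.config
        dt_sub = cfg.substep_dt
        factor = cfg.relaxation_factor
        gravity = cfg.gravity_mm_s2
        movable = self.state.movable[:, None]
        n_contacts = 0
        for _ in range(cfg.substeps):
            x_pre = self.state.x.copy()
            x, v_star = predict(self.state, dt_sub, gravity)
            self.state.v = v_star
            cache = self._detect_substep_contacts(x)
            n_contacts += sum(len(e[1]) for e in cache[0]) + len(cache[1])
            for _ in range(cfg.iterations):
                # precedence: contacts first, then shape-matching clusters
                delta, counts, pair_delta = self._contact_pass(x, x_pre, cache)
                active = counts > 0
                x[active] += (
                    factor * delta[active] / counts[active, None] * movable[active]
                )
                x += factor * pair_delta * movable
                delta, _counts = self._cluster_pass(x)
                x += factor * delta * movable
            self.state.x = x_pre
            finalize(self.state, x, dt_sub, cfg.damping_factor)
            self._cancel_normal_velocity(cache)
        self.sync_clusters()
        self.steps_taken += 1
        self.diagnostics.append(
            {"step": self.steps_taken, "contacts": int(n_contacts)}
        )

    def dump_diagnostics(self, path) -> None:
        """Write the per-step diagnostic log (contact counts) as JSON lines."""
        import json

        with open(path, "w") as fh:
            for record in self.diagnostics:
                fh.write(json.dumps(record) + "\n")

    def run(self, n_steps: int, probe_poses=None) -> None:
        """Run ``n_steps`` steps, optionally setting the probe pose per step.

        ``probe_poses`` is an iterable of (rotation, translation) pairs; a
        pose of None keeps the previous one.
        """
        poses = list(probe_poses) if probe_poses is not None else [None] * n_steps
        if len(poses) != n_steps:
            raise ValueError("one probe pose (or None) per step required")
        for pose in poses:
            if pose is not None and self.scene.probe is not None:
                rotation, translation = pose
                self.scene.probe.set_pose(rotation=rotation, translation=translation)
            self.step()
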