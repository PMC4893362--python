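# Methods

## Model

`pbdtissue` simulates soft-tissue deformation with position-based dynamics
(PBD): the body is a set of `n` spherical particles with positions `x`,
velocities `v` and masses `m`, and material behaviour is imposed by directly
projecting positions onto a set of equality and inequality constraints each
time step, rather than by integrating forces.  A time step consists of
`substeps` sub-iterations of

1. **predict** — symplectic Euler under gravity: `v* = v + Δt g`,
   `x* = x + Δt v*`;
2. **contact detection** — once per substep, contacts are cached for the
   whole substep and re-projected every iteration;
3. **iterate** — a fixed number of constraint-projection iterations
   (Jacobi-style: all constraints see the same positions, their displacement
   contributions are accumulated and then applied together);
4. **finalize** — velocities are recovered from the net displacement,
   `v = Δx/Δt`, then damped.

A single constraint `C(x)` is projected through its Lagrange multiplier

    λ = −C(x) / (∇C M⁻¹ ∇Cᵀ),      Δx = M⁻¹ ∇Cᵀ λ,

the minimum-kinetic-energy displacement satisfying the linearised
constraint (Gauss' principle of least constraint); inequality constraints
project only when violated.  An inverse mass of zero marks a fixed particle.

### Elasticity: clustered shape matching

The elastic response comes from overlapping *shape-matching clusters*.
Cluster centres sit on a regular lattice of pitch
`s = cluster_spacing_factor · r` (r the particle radius) covering the
particle bounding box; each cluster owns the particles inside the cube of
edge `2s` centred on its lattice point, so neighbouring clusters share half
their volume and every particle typically belongs to several clusters.

Each iteration, every cluster rigidly matches its rest shape `x⁰` to the
current positions by minimising `Σ mᵢ ‖R (x⁰ᵢ − x⁰_cm) + x_cm − xᵢ‖²`,
where the translations are the mass-weighted centres of mass.  The optimal
`R` is the rotation (polar) factor of the moment matrix
`A = Σ mᵢ (xᵢ − x_cm)(x⁰ᵢ − x⁰_cm)ᵀ`, computed by SVD with a reflection fix
(the singular direction with the smallest singular value is flipped when
`det < 0`).  The cluster pulls each member a fraction α ∈ [0, 1] of the way
towards its goal `gᵢ = R (x⁰ᵢ − x⁰_cm) + x_cm`; α is the material stiffness
and the parameter the calibration estimates.  Because the mass-weighted mean
of the goals equals the current centre of mass, the raw update conserves
linear momentum exactly, and repeated application never increases the match
residual for any α ∈ [0, 1] — the source of the scheme's unconditional
stability.

α is applied per iteration without iteration-count compensation, so the
*realised* stiffness depends on the iteration and substep counts; α is only
meaningful in the context of those settings and is calibrated under them.

### Averaging and momentum conservation

Within an iteration, constraints are processed in precedence groups —
contacts first, then clusters, so stiffness updates cannot re-embed
particles in obstacles.  Accumulated displacements are applied as
`Δxᵢ · factor/nᵢ` with `nᵢ` the number of constraints touching particle `i`
("local" relaxation, factor 1) or `w/nᵢ` with `w ∈ [1, 2]` ("global"
successive over-relaxation); this is the behaviour of the generic
`solver.iterate` machinery.

For the soft-body pipeline the per-particle division is refined in two
places, because dividing the two sides of an internal constraint by
*different* counts injects net momentum (in early experiments the resting
organ crept sideways at a steady rate, driven purely by this asymmetry):

* **particle–particle contacts**: both partners of a pair are normalised by
  the pair's shared count `max(nᵢ, nⱼ)`;
* **clusters**: each cluster's whole contribution is scaled by
  `1 / max_{i∈cluster} nᵢ` (membership counts).

Both rules conserve momentum exactly per constraint and relax at least as
strongly as the per-particle rule (`Σ_c 1/n̂_c ≤ 1` for every particle), so
the stability guarantee is unchanged.  Single-particle constraints (contacts
with static or kinematic obstacles) keep the plain per-particle division —
there the "momentum leak" is the physical reaction of the obstacle.

### Contacts

Three obstacle primitives are supported; a particle of radius `r` contacts a
shape when its signed distance falls strictly below `r`:

* **static planes** — signed distance `n·x − d`;
* **kinematic convex shapes** (the ultrasound probe, a cuboid) — an
  intersection of half-spaces; inside, the signed distance is the maximum
  half-space distance (exact); outside, shapes built as oriented boxes use
  the exact box closest point, generic half-space lists fall back to the
  maximum-plane value (exact in face regions, a lower bound near edges).
  The probe is kinematic: its pose is prescribed per step and contacts never
  alter it;
* **static triangle meshes** (the support) — nearest-triangle distance with
  the sign from the angle-weighted pseudonormal of the closest feature
  (face, edge or vertex), which is robust for closed meshes.  Candidate
  (particle, triangle) pairs are found through a precomputed voxel hash over
  padded triangle boxes and cached per substep, so per-iteration
  re-projection needs no spatial query.

Projection moves the particle to exactly one radius from the surface along
the contact normal; a tangential correction opposes the particle's slide
during the substep, capped Coulomb-style at μ·|Δx_n| (shape friction 0.35
against obstacles, particle friction 0.25 between particles).  After the
position solve of each substep a velocity-level pass removes the normal
velocity component at still-active contacts (zero restitution); without it,
position projection converts residual penetration into separating velocity
and resting piles jitter indefinitely.

### Damping

Velocity damping is the exponential decay `v ← v · max(0, 1 − k Δt)` applied
at finalize with `k` the damping factor (default 12 s⁻¹).  The clamp at zero
makes the rule stable for any Δt.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `dt` | 1/60 s | frame time step |
| `substeps` | 3 | sub-iterations per step; collision detection once per substep |
| `iterations` | 9 | constraint-projection passes per substep |
| `cluster_spacing_factor` | 3.33 | cluster lattice pitch in particle radii |
| `volume_sampling_factor` | 4 | candidate density of interior sampling; grid pitch `h = 2r/f^(1/3)` |
| `relaxation_mode` / factor | local / 1.0 | Jacobi averaging rule (global mode: SOR `w ∈ [1,2]`) |
| `gravity` | 9.81 m/s² | along −z; 9810 mm/s² internally |
| `density` | 1.05 g/cm³ | tissue density; 1.05·10⁻³ g/mm³ internally |
| `shape_friction` | 0.35 | Coulomb coefficient against obstacles |
| `particle_friction` | 0.25 | Coulomb coefficient between particles |
| `damping_factor` | 12.0 s⁻¹ | exponential velocity decay rate |
| `particle_radius` | 2.7 mm | collision/sampling radius |
| `alpha` | 0.5 | cluster stiffness in [0, 1]; the calibrated parameter |

All geometry is handled in a millimetre–gram–second unit system (CT volumes
and surgical meshes are naturally in mm); the config converts the
conventional quotation units on access.  Voxel centres anchor the image
affine, with 0-based indices.

## Particle sampling

Candidates are placed at the centres of interior voxels of a grid with pitch
`h = 2r / volume_sampling_factor^{1/3}` (interior test: vectorised
ray-crossing parity, written in-package because no installed spatial-index
backend was available for the mesh library's ray queries), optionally plus
uniform random surface samples.  Greedy acceptance in deterministic
lexicographic order removes candidates within `2r` of an accepted particle
(non-overlapping spheres), yielding a maximal set.  Masses are uniform,
`m = ρ·V/n`, so total mass is exact.  Particle and cluster counts are
non-increasing in the particle radius.

## Skinning and ultrasound reslicing

Surface vertices, fiducials and the vertices of a coarse tetrahedral lattice
are bound to their four nearest cluster frames with weights
`w_k ∝ 1/(d_k² + ε)` (ε = 10⁻⁶ mm² guards the zero-distance case),
normalised to one; a point's deformed position is
`Σ_k w_k (R_k · offset_k + com_k)`.  When all clusters carry one rigid
transform, skinning reproduces it exactly.

The tetrahedral lattice splits each cube of a regular grid (default spacing
4 particle radii) into five tetrahedra, mirrored on odd-parity cells so
faces conform; cells that cannot intersect the organ are discarded, and the
retained tetrahedra cover the organ volume.  A 2D ultrasound plane is
resliced by locating each pixel centre barycentrically in the *deformed*
tetrahedra (ties on shared faces go to the lowest tetrahedron id), applying
the same barycentric weights to the *rest* vertices, and sampling the
preoperative volume trilinearly at the resulting rest-space point; pixels
outside every tetrahedron receive a background sentinel.  The image is a
purely geometric resample — no acoustic modelling (attenuation, speckle,
shadowing) is attempted.

## Synthetic phantom

The phantom stands in for a bench experiment on a real organ: a smooth
triangulated ellipsoid at kidney scale (default 110 × 60 × 40 mm), resting
in a closed support slab whose top is a shallow mould of the organ's lower
surface (emulating a plasticine bed; the mould is offset outward along the
surface normal by the particle radius so the particle representation starts
unpenetrated), a kinematic cuboid probe tangent to the upper surface, 45
fiducial beads jitter-spaced along straight interior threads at least ~3 mm
inside the surface, and a synthetic CT volume (1 mm voxels) with two nested
ellipsoidal compartments of distinct intensity.  Generation is pure in
(parameters, seed).

What the phantom does *not* emulate: real kidney anatomy and CT intensity
statistics, deformability of the support (plasticine is rigid here), probe
tilt, and segmentation noise in the fiducial reference.  Passing tests on
the phantom therefore demonstrate the mechanics, calibration and reslicing
machinery — not anatomical accuracy on real organs.

Under gravity the organ settles into the mould during warm-up (a few mm of
centre-of-mass drop and sag); deformation is therefore measured relative to
the recorded post-warm-up (stage-0) state, which plays the role of gravity
compensation.  A slow residual rigid wander of the resting body (sub-mm per
hundred steps, from the asymmetry of the sampled particle set against the
support) remains; it cancels out of the calibration objective because every
α evaluation replays the identical protocol.

## Calibration

The staged indentation protocol: 120 warm-up steps at the tangent (stage-0)
probe pose, record skinned fiducials; then for each deformation stage the
probe pose is interpolated linearly over 90 steps and the fiducials recorded
again (stage depths default to 5.95, 9.48 and 12.38 mm of cumulative
indentation).  The per-stage error statistics are the mean, population
standard deviation and maximum of the per-fiducial Euclidean distances to
the reference, plus the mean as a percentage of the cumulative depth
(undefined at depth 0).

The stiffness is estimated by exhaustive 1-D search: for each α on a grid
(default 0.05…1.00, step 0.05) the protocol is re-simulated from the
identical rest state and the objective — the unweighted mean of the
per-stage mean errors over the *deformed* stages (the rest stage can be
included by flag) — is evaluated.  The chosen optimum is the raw grid
argmin, ties broken towards the stiffer α; a least-squares quartic in α is
fitted for smoothing/diagnostics, its argmin taken over the grid's closed
range via the fit's critical points and endpoints (near-ties at round-off
level go to the left endpoint).  The reference path is single-threaded and
deterministic, so a reference generated by the simulator itself is recovered
exactly.

## Numerical choices

* Polar decomposition by SVD with reflection correction; rank-deficient
  moment matrices (collinear/coincident clusters) are re-solved with a tiny
  bias towards the previous step's rotation (warm start, identity on the
  first step), which resolves the undetermined axis with temporal coherence.
* Contact boundary convention is strict (`distance < radius`); detection
  uses a 0.5 r margin so cached pairs stay valid while positions move within
  the substep.
* Barycentric point location accepts coordinates down to −10⁻⁹ and assigns
  face ties to the lowest tetrahedron id.
* Quartic-fit and grid argmins break exact ties deterministically (left
  endpoint for the fit, stiffer α for the grid).
* Degenerate inputs are total: zero moment matrices return the warm-start
  rotation, zero-gradient constraints are skipped for the iteration,
  far-away planes produce no contacts.

## Problem sizes

The test suite and the acceptance script run a reduced phantom
(80 × 50 × 32 mm, ≈350 particles / ≈190 clusters at the default radius) for
the protocol, calibration and stability experiments; this size keeps a
complete calibration sweep (20 grid points × 390 steps each) at desk scale.
The full-scale phantom (110 × 60 × 40 mm, ≈700 particles) is the default of
`make_phantom`.  The mechanics are size-independent; larger scenes only
change constants.

## Known limitations

* Realised stiffness couples to Δt, iteration, substep and cluster counts;
  a calibrated α is only transferable between runs with identical settings.
* Generic convex shapes (not built as boxes) underestimate the exterior
  distance near edges; contacts there activate marginally early.
* The support is rigid; a deformable (plasticine-like) boundary condition
  is not modelled.
* No self-collision beyond particle–particle spheres, no continuous
  collision detection: a sufficiently fast obstacle could tunnel between
  substeps (a static floor plane in the phantom scene bounds the failure
  mode).
* The ultrasound image is a geometric reslice of the volume, not an
  acoustic simulation.
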