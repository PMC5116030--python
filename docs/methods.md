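# Methods

## Model class

`mbrdme` simulates the reaction–diffusion master equation (RDME): the domain
Ω is partitioned into K voxels, the state is the K×S matrix of copy numbers,
chemical reactions fire inside voxels with mass-action propensities
(zeroth order k·V_i, unimolecular k·x, heterobimolecular k·x_A·x_B/V_i,
homodimerization k·x_A(x_A−1)/(2V_i); total reactant order ≤ 2), and
diffusion is a Markov jump process between voxels with per-molecule
propensities d_ij chosen as a consistent local discretization of the
diffusion equation.  The distinguishing feature is support for domains whose
boundary moves under a user-supplied, biochemistry-dependent velocity field.

Units: lengths μm, times s, diffusion μm²/s, bimolecular rate constants
μm³/s.  No unit conversion happens inside the engine.

## Meshes and jump coefficients

Two voxel conventions are used, both standard for RDME solvers:

* **1D interval meshes are cell-centered**: K uniform cells of width h; the
  jump rate between neighbors is D/h² (nonuniform case: the two-point
  finite-volume rate 2D/(h_i(h_i+h_j))).  Voxel 0 carries the `boundary`
  label (the reactive end).
* **3D tetrahedral meshes are vertex-centered**: voxels are the dual volumes
  of mesh vertices, with volumes from the lumped (row-sum) P1 finite-element
  mass matrix, and jump rates d(i→j) = D·max(−S_ij, 0)/V_i from the P1
  stiffness matrix S.  Positive off-diagonal stiffness entries (non-Delaunay
  edges) would give negative propensities; they are clipped to zero and
  counted (`JumpMatrix.n_clipped`), the standard remedy at the cost of some
  local discretization error.  Membrane-restricted species diffuse on the
  boundary triangulation: the same construction with the surface P1
  stiffness matrix and lumped vertex areas.

Ball meshes are built deterministically from `resolution` icosahedral
subdivisions of the sphere and `resolution + 1` concentric shells; prisms
between shells are split into tetrahedra with the index-based diagonal rule
(Dompierre et al.) so the mesh conforms.  At resolution 2 the mesh volume is
within 3.5 % of the sphere; the deficit shrinks roughly like the square of
the surface edge length.

`quality_check` reports cell-volume extrema and a worst aspect ratio —
max/min width in 1D, circumradius/inradius normalized by the regular
tetrahedron's value in 3D (so a regular tet scores 1.0) — and flags a mesh
when the worst aspect exceeds a configurable threshold (default 10) or any
volume is ≤ 0.  The splitting drivers abort on a flagged mesh, returning the
trajectory up to that point together with the diagnostic.

## Exact simulation (NSM)

`nsm_run` is a Next Subvolume Method: per-voxel next-event times in an
indexed binary min-heap (O(log K) updates); within the firing voxel the
event is chosen Direct-Method style, first between the reaction and
diffusion channel groups, then linearly within the group.  After a reaction
event only the firing voxel is updated; after a diffusion event both the
source and destination voxels are.  Updated voxels draw *fresh* exponential
next-event times rather than reusing rescaled ones — statistically identical
by memorylessness and simpler to reason about.  Sampling is passive: states
are recorded whenever the next event time passes a sample time, so adding
sample times never perturbs the event sequence.

The event loop is a numba kernel operating on flat arrays; the
`numpy.random.Generator` is passed in and its bit-generator state advances
in place, so a snapshot/restore of that state replays a bit-identical event
sequence (verified by test).  All randomness in a simulation flows through
one PCG64 generator seeded from the run configuration.

Geometry-dependent reaction rates are supported through an optional
`rate_hook(mesh, voxel)` multiplier evaluated whenever propensities are
rebuilt; the 1D benchmark uses it for the mesoscopic binding rate k_a/h,
which therefore tracks the current voxel width on a stretching mesh.

## Operator splitting on a moving domain

Per step of length τ: simulate the RDME on the frozen mesh; evaluate the
velocity field from the state history (the contract is
`field(history, mesh, t) → one velocity vector per vertex`); move every
vertex by τ·v (forward Euler); redistribute the particles to the moved mesh;
rebuild jump rates and hook-dependent reaction rates.  Splitting assumes
diffusion is fast compared with boundary motion; the error grows with both
the boundary speed and τ, which is what the convergence tests measure.

**Redistribution** gives every molecule a position sampled uniformly from
its voxel — in 3D from a sphere of equivalent volume centered on the voxel
center, since dual-voxel boundaries are awkward on unstructured meshes —
and reassigns it to the nearest admissible voxel of the new mesh (cKDTree
per restriction label; the scalar `nearest_voxel` query breaks ties toward
the lowest index).  Species restricted to a subdomain are assigned only
among voxels of that subdomain; positions falling outside the new domain go
to the closest admissible voxel.  Totals are conserved exactly by
construction.  Particles are processed species-major in deterministic
(species, voxel, copy) order so each species is one vectorized batch; any
fixed order is equivalent for reproducibility, which is the point of fixing
one.

**Adaptive stepping** (`run_adaptive`): each NSM invocation samples the
state at τ·{1/8, 1/4, 1/2, 1}.  If the step's boundary displacement
d = ‖v‖∞·τ (max over all vertices and components) exceeds `d_max`, τ is
halved and the velocity re-evaluated from the already-sampled
shorter-horizon state — up to three halvings cost no recomputation; beyond
that the pre-step generator state is restored and the biochemistry replayed
over the shorter interval, which reproduces the identical event prefix.
τ_next is the accepted (reduced) τ after a rejection, and doubles after a
first-pass acceptance with τ < τ_split, capped at τ_split.  τ underflow
below τ_split·2⁻¹⁰ (configurable) aborts with a diagnostic.  When a
shortened horizon is accepted without replay, the generator simply carries
the state it reached — the discarded draws are independent of all future
draws, so no bias is introduced.

## Microscale reference (1D Brownian dynamics)

`bd_run` integrates free particles with Euler–Maruyama steps of variance
2·D·dt in [L(t), R]; the right end reflects specularly.  A particle whose
proposed position touches or crosses the left end binds with the
reactive-boundary probability P = k_a·√(π·dt/D) (the Erban–Chapman
calibration of a Robin constant k_a) and otherwise reflects specularly.
Bound particles unbind with per-step probability 1−exp(−k_d·dt)
(implemented exactly as a geometric step count) and re-enter at the current
L; the boundary is frozen during a step and advanced by −v·dt afterwards.
The precondition P < 0.1 is enforced; for the benchmark rates (k_a = 50,
D = 1) this requires dt < 1.27·10⁻⁶ s, and the default is dt = 10⁻⁶ s.
The scheme's O(√dt) bias is visible in the equilibrium bound fraction:
about +7·10⁻⁴ at dt = 10⁻⁶ and statistically indistinguishable from zero at
dt = 2.5·10⁻⁷ (which the equilibrium-consistency test therefore uses).
Desorbed particles re-enter exactly at L, the simplest choice consistent
with the scheme; the associated error is part of the O(√dt) term.

The mesoscopic counterpart of the boundary chemistry on a mesh of end-voxel
width h is k_a_meso = k_a/h and k_d_meso = k_d (`micro_to_meso_rates`).

## The polarization circuit and the density switch

The minimal positive-feedback circuit on a spherical cell:

    Cdc42c → Cdc42m            k_on   (attachment, boundary voxels only)
    Cdc42m → Cdc42c            k_off  (detachment)
    Cdc42c + Cdc42m → 2 Cdc42m k_fb   (recruitment, boundary voxels,
                                       volume-scaled per voxel)

Cytosolic Cdc42 diffuses everywhere at D_cyt; membrane-bound Cdc42 diffuses
on the boundary at D_mem.  Bimolecular recruitment fires in boundary voxels,
where both partners coexist in the vertex-centered dual volume.

Mean-field analysis of the totals (c cytosolic, m membrane, V cell volume,
V_m the boundary-voxel volume): dm/dt = k_on·c·V_m/V + k_fb·c·m/V − k_off·m.
The m ≈ 0 state loses stability when k_fb·N/V > k_off, i.e. below the
critical volume V_c = N·k_fb/k_off; above it the membrane pool collapses to
the small k_on-balanced value, and the circuit polarizes only in the
stochastic, subcritical regime.  `critical_radius(N, ratio)` solves
(4/3)πr³ = N/ratio, the convention that reproduces the reported critical
radius 6.425 μm for N = 1000 and ratio 0.9 — coherent with the stability
analysis when `ratio` is read as k_off/k_fb.  The package's default
parameters are chosen accordingly (k_off = 0.9 s⁻¹, k_fb = 1.0 μm³/s,
k_on = 0.01 s⁻¹, D_cyt = 10 μm²/s, D_mem = 0.01 μm²/s, N = 1000), placing
the physical switch of the default model exactly at 6.425 μm.  k_on is kept
two orders below k_off so spontaneous attachment seeds clusters without
washing out polarization; the diffusion constants are typical cytosolic and
membrane-protein mobilities.

`meanfield_steady_state` integrates exactly these restriction-aware rate
equations (LSODA in expanding windows until the residual rate of change per
unit time drops below 10⁻¹⁰ relative); it is the oracle the supercritical
simulations are compared against.  With V_m = V it reduces to the classic
well-mixed two-state balance k_on/(k_on + k_off).

## Velocity fields

* `radial_velocity_field(rate)`: boundary vertices move radially at `rate`;
  the interior uses the uniform scaling v(x) = rate·x/R, which is the
  harmonic extension of the boundary data and keeps the mesh geometrically
  similar, so the outer radius grows at exactly `rate`.
* `tip_growth_velocity_field_for(network, params)`: the boundary voxel with
  the highest tracked-species concentration (ties → lowest index) defines
  the growth site; its area-weighted outward normal n̂ the direction.  Every
  boundary vertex moves parallel to n̂ at v_max·exp(−d²/(2σ²)) with d its
  distance to the site; the interior field is the graph-Laplacian harmonic
  extension (`extend_velocity_to_interior`, solved directly; constant
  boundary data extends to that constant).  Zero tracked molecules give a
  zero field.  Defaults v_max = 10 nm/s, σ = 1 μm are plausible
  tip-growth scales; the surrogate biochemistry is the polarization circuit
  above.

## Study conditions and problem sizes

The validation studies are generated entirely from parameters, no external
data:

* 1D benchmark: k_a = 50 μm/s, k_d = 1 s⁻¹, D = 1 μm²/s, domain [0, 1],
  left end moving at −v, T = 1 s, N_vox ∈ {5, 20, 50}, Δt_split ∈
  [0.01, 0.2].  The test suite runs 10⁴ molecules with ≥ 20 replicates per
  grid cell (the full-scale study at 10⁶ molecules is an explicit opt-in via
  the CLI `--n-molecules`); replicate count compensates for the smaller
  ensembles, and KS errors are averaged per replicate rather than pooled.
* Polarization switch: N = 1000 molecules, static spheres at r = 3 μm
  (subcritical) and 9 μm (supercritical), 60 s horizons; the expanding run
  grows r = 4.5 → 8.5 μm at dr/dt = 50 nm/s with τ_split = 20 s after a
  30 s polarized burn-in.

What these conditions do not emulate: real cytosolic crowding, anisotropic
or state-dependent diffusion, mechanics (velocity fields are prescribed
functions, not solved), and the full Cdc42 GTPase cycle — the circuit here
is the minimal switch, so passing tests demonstrate correctness of the
numerical method and the switch phenomenology, not quantitative yeast
biology.

## Numerical choices

* Nearest-voxel ties break toward the lowest index; the maximum-polarization
  site likewise.
* Negative-propensity clipping as described; the clipped count is reported
  rather than hidden.
* Adaptive-step floor τ_split·2⁻¹⁰; aspect-ratio flag threshold 10.
* Channel selection guards against float roundoff by falling back to the
  last live channel of a group.
* Degenerate inputs: zero-diffusion species get empty jump matrices; empty
  sample sets, inverted cells, absent restriction labels, and reaction
  orders > 2 raise typed errors.
* The CME birth–death exactness check compares the voxel-0 marginal against
  its product-Poisson stationary law at 10⁵ samples spaced two relaxation
  times apart (total-variation tolerance 0.02 includes the finite-sample
  noise floor of ~0.01).

## Known limitations

* Operator splitting is first order in τ; there is no tighter
  mechanics–biochemistry coupling within a step.
* No remeshing or refinement: sustained anisotropic growth (long tip-growth
  runs) eventually degrades element quality until the quality gate aborts.
* The equivalent-sphere position sampling induces spatial error proportional
  to mesh anisotropy; on very distorted meshes redistribution can leak mass
  between nearby subdomain voxels faster than physical diffusion would.
* The BD solver is 1D only, by design — it exists as the microscale oracle
  for the benchmark geometry.
* Bimolecular propensities assume locally well-mixed voxels; voxels much
  smaller than a reaction radius would need microscale corrections that are
  out of scope here.
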