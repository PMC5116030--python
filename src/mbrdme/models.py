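"""Builders for the benchmark and yeast-polarization model systems.

* :func:`make_example1` — one species in a 1D interval binding to a moving
  reactive left end (the mesoscale/microscale convergence benchmark).
* :func:`make_polarization_model` — the minimal positive-feedback circuit for
  Cdc42 polarization on a spherical cell: cytosolic Cdc42 attaches to the
  membrane spontaneously (k_on), detaches (k_off), and is recruited by
  membrane-bound Cdc42 (k_fb).  The circuit has a density-dependent switch:
  polarization exists only while the molecule density is high enough, so a
  growing cell switches it off when its volume crosses N·k_off/k_fb.
* velocity-field constructors for a uniformly expanding sphere and for
  polarization-directed tip growth, and a mean-field steady-state oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .mesh import BOUNDARY, Mesh, build_ball_mesh, build_interval_mesh
from .moving import BoundaryVelocityField, extend_velocity_to_interior
from .nsm import InvalidModelError, Reaction, ReactionNetwork, Species, SystemState


@dataclass
class PolarizationParams:
    """Parameters of the positive-feedback polarization circuit.

    Defaults put the physical critical radius of the density switch for
    N_total = 1000 at 6.425 μm (critical volume N·k_fb/k_off).
    """

    k_on: float = 0.01          # 1/s, spontaneous membrane attachment
    k_off: float = 0.9          # 1/s, detachment
    k_fb: float = 1.0           # μm³/s, feedback recruitment
    D_cyt: float = 10.0         # μm²/s
    D_mem: float = 0.01         # μm²/s
    N_total: int = 1000
    radius: float = 4.0         # μm

    def __post_init__(self):
        if min(self.k_on, self.k_off, self.k_fb, self.D_cyt, self.D_mem) < 0:
            raise ValueError("rates and diffusion constants must be >= 0")
        if self.N_total < 0 or self.radius <= 0:
            raise ValueError("need N_total >= 0 and radius > 0")


@dataclass
class TipGrowthParams:
    tracked_species: str = "Cdc42m"
    v_max: float = 0.01         # μm/s
    sigma: float = 1.0          # μm, Gaussian attenuation width

    def __post_init__(self):
        if self.v_max < 0 or self.sigma <= 0:
            raise ValueError("need v_max >= 0 and sigma > 0")


# ---------------------------------------------------------------------------
# Example 1: 1D reactive moving boundary


def make_example1(
    n_vox: int,
    k_a: float = 50.0,
    k_d: float = 1.0,
    D: float = 1.0,
    v: float = 0.5,
) -> tuple[Mesh, ReactionNetwork, "callable", BoundaryVelocityField]:
    """1D benchmark: species S in [0, 1], reactive left end moving at −v.

    Free S diffuses with constant ``D``; it binds in the leftmost voxel at the
    mesoscopic rate k_a/h (h = current leftmost voxel width, refreshed through
    the geometry hook whenever propensities are rebuilt) and unbinds at k_d.
    Returns (mesh, network, initial_state builder, velocity field); the
    builder maps a total molecule count (and optional rng for multinomial
    placement) to a uniform initial state of free S.
    """
    mesh = build_interval_mesh(0.0, 1.0, n_vox)
    species = [
        Species("S", diffusion_constant=D),
        Species("S_b", diffusion_constant=0.0, subdomain_restriction=BOUNDARY),
    ]
    reactions = [
        Reaction(
            {"S": 1}, {"S_b": 1}, rate_constant=k_a, subdomain=BOUNDARY,
            rate_hook=lambda m, i: 1.0 / m.voxel_volumes[i], name="bind",
        ),
        Reaction({"S_b": 1}, {"S": 1}, rate_constant=k_d, name="unbind"),
    ]
    network = ReactionNetwork(species, reactions)

    def initial_state(n_molecules: int, rng: np.random.Generator | None = None) -> SystemState:
        counts = np.zeros((mesh.n_voxels, 2), dtype=np.int64)
        if rng is None:
            base, extra = divmod(n_molecules, n_vox)
            counts[:, 0] = base
            counts[:extra, 0] += 1
        else:
            w = mesh.voxel_volumes / mesh.total_volume()
            counts[:, 0] = rng.multinomial(n_molecules, w)
        return SystemState(counts)

    def velocity(history, current_mesh: Mesh, t: float) -> np.ndarray:
        x = current_mesh.vertex_coords[:, 0]
        left, right = x.min(), x.max()
        field = np.zeros_like(current_mesh.vertex_coords)
        field[:, 0] = -v * (right - x) / (right - left)
        return field

    return mesh, network, initial_state, velocity


# ---------------------------------------------------------------------------
# Example 2: density-dependent polarization switch on a sphere


def make_polarization_model(
    params: PolarizationParams, resolution: int = 2
) -> tuple[Mesh, ReactionNetwork, "callable"]:
    """Positive-feedback Cdc42 circuit on a ball mesh of ``params.radius``.

    Species: Cdc42c (cytosolic, D_cyt, everywhere) and Cdc42m (membrane-bound,
    D_mem, restricted to boundary voxels).  Reactions (attachment and
    recruitment fire only in boundary voxels, where cytosol and membrane
    coexist):

        Cdc42c          → Cdc42m              k_on
        Cdc42m          → Cdc42c              k_off
        Cdc42c + Cdc42m → 2 Cdc42m            k_fb (volume-scaled)

    The builder distributes N_total copies of Cdc42c over voxels (multinomial
    by volume when given an rng, largest-remainder rounding otherwise).
    """
    mesh = build_ball_mesh(params.radius, resolution)
    if len(mesh.voxels_in(BOUNDARY)) == 0:
        raise InvalidModelError("mesh has no boundary voxels for the membrane")
    species = [
        Species("Cdc42c", diffusion_constant=params.D_cyt),
        Species("Cdc42m", diffusion_constant=params.D_mem, subdomain_restriction=BOUNDARY),
    ]
    reactions = [
        Reaction({"Cdc42c": 1}, {"Cdc42m": 1}, params.k_on, subdomain=BOUNDARY, name="attach"),
        Reaction({"Cdc42m": 1}, {"Cdc42c": 1}, params.k_off, name="detach"),
        Reaction(
            {"Cdc42c": 1, "Cdc42m": 1}, {"Cdc42m": 2}, params.k_fb,
            subdomain=BOUNDARY, name="recruit",
        ),
    ]
    network = ReactionNetwork(species, reactions)

    def initial_state(rng: np.random.Generator | None = None) -> SystemState:
        counts = np.zeros((mesh.n_voxels, 2), dtype=np.int64)
        w = mesh.voxel_volumes / mesh.total_volume()
        if rng is None:
            ideal = params.N_total * w
            counts[:, 0] = np.floor(ideal).astype(np.int64)
            rem = params.N_total - counts[:, 0].sum()
            order = np.argsort(-(ideal - np.floor(ideal)))
            counts[order[:rem], 0] += 1
        else:
            counts[:, 0] = rng.multinomial(params.N_total, w)
        return SystemState(counts)

    return mesh, network, initial_state


def critical_radius(n_total: float, ratio_fb_off: float) -> float:
    """Critical sphere radius (μm) of the density-dependent polarization switch.

    Solves (4/3)·π·r³ = N / ratio for the critical volume of the switch; at
    volumes above it the feedback can no longer hold molecules on the
    membrane and polarization collapses.
    """
    if n_total < 0:
        raise ValueError("n_total must be >= 0")
    if ratio_fb_off <= 0:
        raise ValueError("rate ratio must be > 0")
    v_crit = n_total / ratio_fb_off
    return float((3.0 * v_crit / (4.0 * np.pi)) ** (1.0 / 3.0))


def membrane_volume(mesh: Mesh) -> float:
    """Total dual volume of the boundary (membrane) voxels (μm³)."""
    return float(mesh.voxel_volumes[mesh.voxels_in(BOUNDARY)].sum())


def radial_velocity_field(rate_dr_dt: float) -> BoundaryVelocityField:
    """Uniform radial expansion (rate > 0) or contraction of a ball mesh.

    Every boundary vertex moves along its unit radial direction at
    ``rate_dr_dt``; the interior follows the uniform radial scaling
    v(x) = rate·x/R (the harmonic extension of the boundary data), so the
    mesh stays geometrically similar and the outer radius changes at exactly
    ``rate_dr_dt`` per unit time.  A vertex at the origin is left fixed.
    """
    if not np.isfinite(rate_dr_dt):
        raise ValueError("rate must be finite")

    def velocity(history, mesh: Mesh, t: float) -> np.ndarray:
        radii = np.linalg.norm(mesh.vertex_coords, axis=1)
        r_outer = radii.max()
        if r_outer == 0:
            return np.zeros_like(mesh.vertex_coords)
        return rate_dr_dt * mesh.vertex_coords / r_outer

    return velocity


def tip_growth_velocity_field(params: TipGrowthParams) -> BoundaryVelocityField:
    """Boundary growth at the point of maximum polarization.

    The boundary voxel with the highest tracked-species concentration
    (count per voxel volume; ties broken toward the lowest index) defines the
    growth site; its outward normal n̂ (area-weighted average of adjacent
    boundary facet normals) sets the direction.  Every boundary vertex moves
    parallel to n̂ with speed v_max·exp(−d²/(2σ²)), d its distance to the
    growth site; the interior field is the harmonic extension.  With zero
    tracked molecules the field is identically zero.
    """

    def velocity(history, mesh: Mesh, t: float) -> np.ndarray:
        state: SystemState = history[-1][1]
        try:
            col = [i for i, lbl in enumerate(_species_names_cache(history))
                   if lbl == params.tracked_species][0]
        except IndexError:
            raise InvalidModelError(
                f"tracked species {params.tracked_species!r} not in state history"
            ) from None
        return _tip_growth_field(mesh, state.counts[:, col], params)

    return velocity


def _species_names_cache(history):
    # The velocity-field contract carries only states; the tracked column is
    # resolved by the caller-facing wrapper below when a network is available.
    raise InvalidModelError("use tip_growth_velocity_field_for(network, params)")


def tip_growth_velocity_field_for(
    network: ReactionNetwork, params: TipGrowthParams
) -> BoundaryVelocityField:
    """Tip-growth field bound to ``network`` (resolves the tracked species)."""
    if params.tracked_species not in network.species_index:
        raise InvalidModelError(f"unknown tracked species {params.tracked_species!r}")
    col = network.index(params.tracked_species)
    spec = network.species[col]
    if spec.subdomain_restriction != BOUNDARY:
        raise InvalidModelError(
            f"tracked species {params.tracked_species!r} must be membrane-restricted"
        )

    def velocity(history, mesh: Mesh, t: float) -> np.ndarray:
        state: SystemState = history[-1][1]
        return _tip_growth_field(mesh, state.counts[:, col], params)

    return velocity


def _tip_growth_field(mesh: Mesh, tracked: np.ndarray, params: TipGrowthParams) -> np.ndarray:
    boundary = mesh.voxels_in(BOUNDARY)
    if tracked.sum() == 0:
        return np.zeros_like(mesh.vertex_coords)
    conc = tracked[boundary] / mesh.voxel_volumes[boundary]
    peak_voxel = int(boundary[int(np.argmax(conc))])  # argmax → lowest index on ties
    peak_point = mesh.voxel_centers[peak_voxel]
    # outward normal: area-weighted over boundary facets touching the peak vertex
    facet_mask = np.any(mesh.boundary_facets == peak_voxel, axis=1)
    from .mesh import _tri_areas_normals

    areas, normals = _tri_areas_normals(mesh.vertex_coords, mesh.boundary_facets[facet_mask])
    n_hat = (normals * areas[:, None]).sum(axis=0)
    n_hat /= np.linalg.norm(n_hat)
    bverts = mesh.boundary_vertices
    d = np.linalg.norm(mesh.vertex_coords[bverts] - peak_point, axis=1)
    speeds = params.v_max * np.exp(-(d ** 2) / (2.0 * params.sigma ** 2))
    return extend_velocity_to_interior(mesh, speeds[:, None] * n_hat[None, :])


# ---------------------------------------------------------------------------
# mean-field steady-state oracle


def meanfield_steady_state(
    network: ReactionNetwork,
    total_volume: float,
    membrane_volume: float,
    n_total: float,
    rtol: float = 1e-10,
    max_windows: int = 200,
) -> dict[str, float]:
    """Well-mixed mean-field steady state of a copy-conserving network.

    Integrates the deterministic rate equations for the per-species totals,
    accounting for subdomain restrictions: a reaction restricted to the
    membrane sees only the fraction V_m/V of an unrestricted reactant, while
    a membrane-restricted species contributes its full total there.  Returns
    the expected totals once the relative rate of change per unit time drops
    below ``rtol``; raises if that never happens within the step budget.
    """
    if total_volume <= 0 or membrane_volume < 0 or membrane_volume > total_volume:
        raise ValueError("need 0 <= membrane_volume <= total_volume, total_volume > 0")
    S = network.n_species
    restricted = [s.subdomain_restriction != "all" for s in network.species]
    reactions = network.reactions

    def region_volume(r: Reaction) -> float:
        return membrane_volume if r.subdomain != "all" else total_volume

    def available(y, s_idx: int, r: Reaction) -> float:
        # amount of species s inside the reaction's active region
        if r.subdomain == "all" or restricted[s_idx]:
            return y[s_idx]
        return y[s_idx] * membrane_volume / total_volume

    idx = network.species_index

    def rhs(t, y):
        dy = np.zeros(S)
        for r in reactions:
            vr = region_volume(r)
            items = list(r.reactants.items())
            if r.order == 0:
                rate = r.rate_constant * vr
            elif r.order == 1:
                rate = r.rate_constant * available(y, idx[items[0][0]], r)
            elif len(items) == 2:
                rate = (
                    r.rate_constant
                    * available(y, idx[items[0][0]], r)
                    * available(y, idx[items[1][0]], r)
                    / vr
                )
            else:
                a = available(y, idx[items[0][0]], r)
                rate = r.rate_constant * a * a / (2.0 * vr)
            for n, c in r.reactants.items():
                dy[idx[n]] -= c * rate
            for n, c in r.products.items():
                dy[idx[n]] += c * rate
        return dy

    # conservation sanity: every reaction must conserve total copy number
    for r in reactions:
        if sum(r.products.values()) != sum(r.reactants.values()):
            raise InvalidModelError("meanfield oracle requires a copy-conserving network")

    y = np.zeros(S)
    # start with everything in the first unrestricted species (cytosol)
    start = next((i for i in range(S) if not restricted[i]), 0)
    y[start] = float(n_total)
    window = 10.0
    scale = max(float(n_total), 1.0)
    for _ in range(max_windows):
        sol = solve_ivp(rhs, (0.0, window), y, method="LSODA", rtol=1e-12, atol=1e-10 * scale)
        y = sol.y[:, -1]
        if np.linalg.norm(rhs(0.0, y)) < rtol * scale:
            return {s.name: float(y[i]) for i, s in enumerate(network.species)}
    raise RuntimeError("mean-field integration did not reach steady state")
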