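"""Operator-splitting drivers coupling NSM biochemistry to mesh motion.

Each splitting step of length τ: (1) simulate the RDME on the frozen mesh,
(2) evaluate the user-supplied boundary-velocity field from the biochemical
state history, (3) move every mesh vertex by τ·v (forward Euler), and
(4) redistribute the particles onto the moved mesh, rebuilding diffusion jump
rates and geometry-dependent reaction propensities.  The adaptive driver
additionally rejects steps whose maximum boundary displacement ‖v‖∞·τ would
exceed ``d_max``, halving τ and replaying the identical biochemistry over the
shortened interval (the generator state is preserved across rejections).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import Mesh, MeshQualityError, move_mesh, quality_check
from .nsm import (
    ReactionNetwork,
    SystemState,
    build_jump_matrices,
    get_rng_state,
    make_rng,
    nsm_run,
    set_rng_state,
)
from .redistribute import redistribute

logger = logging.getLogger(__name__)

#: fixed interior sample fractions of each splitting interval; they allow the
#: adaptive stepper to halve τ three times without recomputing biochemistry
SAMPLE_FRACTIONS = (0.125, 0.25, 0.5, 1.0)

# A boundary-velocity field maps (state history over [0, t+τ], mesh, time) to
# one velocity vector (μm/s) per mesh vertex.
BoundaryVelocityField = Callable[[list, Mesh, float], np.ndarray]


class StepSizeUnderflowError(RuntimeError):
    pass


@dataclass
class SplitConfig:
    """Operator-splitting configuration.

    ``tau_split``: splitting step (s); ``d_max``: maximum boundary
    displacement per accepted step (μm), enables the adaptive driver;
    ``tau_floor_factor``: abort threshold τ_min = τ_split·factor.
    """

    tau_split: float
    t_final: float
    seed: int = 0
    d_max: float | None = None
    tau_floor_factor: float = 2.0 ** -10
    aspect_threshold: float = 10.0

    def __post_init__(self):
        if self.tau_split <= 0:
            raise ValueError("tau_split must be > 0")
        if self.t_final <= 0:
            raise ValueError("t_final must be > 0")
        if self.d_max is not None and self.d_max <= 0:
            raise ValueError("d_max must be > 0 when present")


@dataclass
class Trajectory:
    """Ordered (time, mesh, state) records plus step diagnostics."""

    times: list[float] = field(default_factory=list)
    meshes: list[Mesh] = field(default_factory=list)
    states: list[SystemState] = field(default_factory=list)
    taus: list[float] = field(default_factory=list)
    rejections: list[int] = field(default_factory=list)
    aborted: str | None = None

    def record(self, t: float, mesh: Mesh, state: SystemState, tau: float, nrej: int) -> None:
        self.times.append(float(t))
        self.meshes.append(mesh.copy())
        self.states.append(state.copy())
        self.taus.append(float(tau))
        self.rejections.append(int(nrej))

    @property
    def final_state(self) -> SystemState:
        return self.states[-1]

    @property
    def final_mesh(self) -> Mesh:
        return self.meshes[-1]


def _velocity_inf_norm(v: np.ndarray) -> float:
    """Max absolute velocity component over every mesh vertex."""
    return float(np.abs(v).max()) if v.size else 0.0


def _advance_geometry(mesh, state, network, v, tau, rng, config, traj, t_new):
    """Move the mesh, check quality, redistribute; returns (mesh, state, jumps)."""
    mesh_new = move_mesh(mesh, v, tau)
    report = quality_check(mesh_new, config.aspect_threshold)
    if report.flagged:
        raise MeshQualityError(
            f"mesh quality failure at t={t_new:.6g}: worst aspect "
            f"{report.worst_aspect:.3g} (cell {report.worst_cell}), "
            f"min volume {report.min_volume:.3g}"
        )
    state_new, diag = redistribute(state, mesh, mesh_new, network, rng)
    logger.debug(
        "t=%.6g tau=%.3g moved=%.3f outside=%.3f", t_new, tau,
        diag.fraction_moved, diag.fraction_outside,
    )
    jumps = build_jump_matrices(mesh_new, network)
    return mesh_new, state_new, jumps


def run_fixed(
    mesh0: Mesh,
    state0: SystemState,
    network: ReactionNetwork,
    velocity: BoundaryVelocityField,
    config: SplitConfig,
) -> Trajectory:
    """Fixed-step operator splitting until ``t_final``.

    On a mesh-quality failure the trajectory computed so far is returned with
    ``aborted`` set to the diagnostic.
    """
    state0.validate(mesh0, network)
    rng = make_rng(config.seed)
    mesh, state = mesh0.copy(), state0.copy()
    jumps = build_jump_matrices(mesh, network)
    traj = Trajectory()
    traj.record(0.0, mesh, state, 0.0, 0)
    history: list[tuple[float, SystemState]] = [(0.0, state)]
    t = 0.0
    eps = 1e-12 * config.t_final
    while t < config.t_final - eps:
        tau = min(config.tau_split, config.t_final - t)
        state = nsm_run(state, mesh, jumps, network, [t + tau], rng, t0=t)[-1]
        history.append((t + tau, state))
        v = np.asarray(velocity(history, mesh, t + tau), dtype=float)
        try:
            mesh, state, jumps = _advance_geometry(
                mesh, state, network, v, tau, rng, config, traj, t + tau
            )
        except MeshQualityError as err:
            traj.aborted = str(err)
            logger.warning("aborting: %s", err)
            return traj
        t += tau
        history[-1] = (t, state)
        traj.record(t, mesh, state, tau, 0)
    return traj


def run_adaptive(
    mesh0: Mesh,
    state0: SystemState,
    network: ReactionNetwork,
    velocity: BoundaryVelocityField,
    config: SplitConfig,
) -> Trajectory:
    """Rejection-based adaptive operator splitting.

    Per step, the RDME is sampled at τ·{1/8, 1/4, 1/2, 1}; if the boundary
    displacement d = ‖v‖∞·τ exceeds ``d_max``, τ is halved and the velocity
    re-evaluated from the already-sampled shorter-horizon state (up to three
    halvings without recomputation; beyond that the pre-step generator state
    is restored and the biochemistry replayed over the shorter interval).
    After a first-pass acceptance with τ < τ_split the next step doubles,
    capped at τ_split.
    """
    if config.d_max is None:
        raise ValueError("run_adaptive requires config.d_max")
    state0.validate(mesh0, network)
    rng = make_rng(config.seed)
    mesh, state = mesh0.copy(), state0.copy()
    jumps = build_jump_matrices(mesh, network)
    traj = Trajectory()
    traj.record(0.0, mesh, state, 0.0, 0)
    history: list[tuple[float, SystemState]] = [(0.0, state)]
    tau_floor = config.tau_split * config.tau_floor_factor
    t = 0.0
    tau = config.tau_split
    eps = 1e-12 * config.t_final
    while t < config.t_final - eps:
        tau = min(tau, config.t_final - t)
        pre_rng = get_rng_state(rng)
        samples = _sampled_interval(state, mesh, jumps, network, t, tau, rng)
        level = len(samples) - 1  # index of the currently accepted horizon
        n_rej = 0
        s_tau, s_state = samples[level]

        def _hist(lvl):
            # accepted history plus every sampled state up to the horizon
            return history + [(t + st, ss) for st, ss in samples[: lvl + 1]]

        v = np.asarray(velocity(_hist(level), mesh, t + s_tau), float)
        d = _velocity_inf_norm(v) * s_tau
        tau_next = tau
        while d > config.d_max:
            n_rej += 1
            new_tau = s_tau / 2.0
            if new_tau < tau_floor:
                traj.aborted = (
                    f"step size underflow at t={t:.6g}: tau={new_tau:.3g} < "
                    f"floor {tau_floor:.3g}"
                )
                logger.warning("aborting: %s", traj.aborted)
                return traj
            if level > 0:
                level -= 1
                s_tau, s_state = samples[level]
            else:
                # more than three halvings: replay the biochemistry from the
                # preserved generator state over the shorter interval
                set_rng_state(rng, pre_rng)
                samples = _sampled_interval(state, mesh, jumps, network, t, new_tau, rng)
                level = len(samples) - 1
                s_tau, s_state = samples[level]
            assert abs(s_tau - new_tau) <= 1e-12 * tau
            v = np.asarray(velocity(_hist(level), mesh, t + s_tau), float)
            d = _velocity_inf_norm(v) * s_tau
            tau_next = s_tau
        if n_rej == 0 and tau < config.tau_split - eps:
            tau_next = min(2.0 * tau, config.tau_split)
        accepted_tau = s_tau
        state = s_state
        try:
            mesh, state, jumps = _advance_geometry(
                mesh, state, network, v, accepted_tau, rng, config, traj, t + accepted_tau
            )
        except MeshQualityError as err:
            traj.aborted = str(err)
            logger.warning("aborting: %s", err)
            return traj
        t += accepted_tau
        history.append((t, state))
        traj.record(t, mesh, state, accepted_tau, n_rej)
        tau = tau_next
    return traj


def _sampled_interval(state, mesh, jumps, network, t, tau, rng):
    """Run the NSM over [t, t+τ] sampling at the fixed interior fractions."""
    times = [t + f * tau for f in SAMPLE_FRACTIONS]
    states = nsm_run(state, mesh, jumps, network, times, rng, t0=t)
    return [(f * tau, s) for f, s in zip(SAMPLE_FRACTIONS, states)]


def extend_velocity_to_interior(mesh: Mesh, boundary_velocities: np.ndarray) -> np.ndarray:
    """Harmonic extension of a boundary vertex field to all vertices.

    Interior values solve the graph-Laplacian (uniform edge weights) Dirichlet
    problem with the boundary values fixed; a constant boundary field extends
    to that constant.  ``boundary_velocities`` has one row per boundary vertex
    in the order of ``mesh.boundary_vertices``.
    """
    bverts = mesh.boundary_vertices
    bvel = np.atleast_2d(np.asarray(boundary_velocities, dtype=float))
    if bvel.shape[0] != len(bverts):
        raise ValueError(
            f"expected {len(bverts)} boundary velocity vectors, got {bvel.shape[0]}"
        )
    n = mesh.n_vertices
    dim = mesh.vertex_coords.shape[1]
    full = np.zeros((n, dim))
    full[bverts] = bvel
    interior = np.setdiff1d(np.arange(n), bverts)
    if len(interior) == 0:
        return full
    # vertex adjacency from cell edges
    pairs = set()
    for cell in mesh.cells:
        for a in range(len(cell)):
            for b in range(a + 1, len(cell)):
                pairs.add((int(cell[a]), int(cell[b])))
    rows = np.array([p[0] for p in pairs] + [p[1] for p in pairs])
    cols = np.array([p[1] for p in pairs] + [p[0] for p in pairs])
    adj = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    if np.any(deg[interior] == 0):
        raise ValueError("mesh has a disconnected interior vertex")
    lap = sp.diags(deg) - adj
    lii = lap[interior][:, interior].tocsc()
    lib = lap[interior][:, bverts]
    rhs = -lib @ full[bverts]
    sol = spla.spsolve(lii, rhs)
    full[interior] = np.atleast_2d(sol.reshape(len(interior), dim))
    residual = np.abs(lii @ full[interior] - rhs).max() if rhs.size else 0.0
    if residual > 1e-8 * max(1.0, np.abs(rhs).max()):
        raise RuntimeError(f"harmonic extension failed to converge: residual {residual:.2e}")
    return full
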