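"""Brownian-dynamics reference solver for the 1D moving-boundary benchmark.

A single species diffuses in [L(t), R]; the left end L(t) = L0 − v·t is a
reactive (absorbing/desorbing) boundary with microscopic association rate
``k_a`` (μm/s, a Robin boundary constant) and dissociation rate ``k_d``
(1/s); the right end reflects.  The Euler–Maruyama scheme uses the
reactive-boundary binding probability k_a·sqrt(π·dt/D) for a particle that
touches or crosses the left end (specular reflection otherwise), which
converges to the Robin condition as dt → 0.

The mesoscopic (RDME) counterpart of this boundary chemistry on a 1D mesh of
voxel width h is a first-order binding channel in the end voxel with rate
k_a_meso = k_a/h and unbinding at k_d_meso = k_d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import bd_kernel


@dataclass
class BDEnsemble:
    """Microscale ensemble: explicit free-particle positions plus a bound pool."""

    free_positions: np.ndarray
    bound_count: int
    D: float
    k_a: float
    k_d: float
    v: float
    R: float
    L: float
    t: float = 0.0

    @property
    def n_particles(self) -> int:
        return len(self.free_positions) + self.bound_count

    @property
    def bound_fraction(self) -> float:
        return self.bound_count / self.n_particles if self.n_particles else 0.0


def micro_to_meso_rates(k_a: float, k_d: float, h: float) -> tuple[float, float]:
    """Convert microscopic boundary rates to mesoscopic end-voxel rates.

    Returns ``(k_a / h, k_d)`` for an end voxel of width ``h``.
    """
    if h <= 0:
        raise ValueError(f"voxel width must be > 0, got {h}")
    if k_a < 0 or k_d < 0:
        raise ValueError("rates must be >= 0")
    return k_a / h, k_d


def max_stable_dt(k_a: float, D: float, p_max: float = 0.1) -> float:
    """Largest dt_bd with per-contact binding probability below ``p_max``."""
    if k_a == 0:
        return np.inf
    return (p_max / k_a) ** 2 * D / np.pi


def bd_run(
    n_particles: int,
    *,
    D: float,
    k_a: float,
    k_d: float,
    v: float,
    R: float,
    t_final: float,
    dt_bd: float = 1e-6,
    rng: np.random.Generator,
    L0: float = 0.0,
    initial_positions: np.ndarray | None = None,
    initial_bound: int = 0,
) -> BDEnsemble:
    """Run the Brownian-dynamics ensemble until ``t_final``.

    Free particles start at ``initial_positions`` (default: uniform on
    [L0, R]); ``initial_bound`` particles start bound, with exponentially
    distributed residual binding times.  Enforces the step-size precondition
    k_a·sqrt(π·dt_bd/D) < 0.1.
    """
    if D <= 0:
        raise ValueError("D must be > 0")
    p_bind = k_a * np.sqrt(np.pi * dt_bd / D)
    if p_bind >= 0.1:
        raise ValueError(
            f"dt_bd={dt_bd:g} too large: k_a*sqrt(pi*dt/D)={p_bind:.3f} >= 0.1; "
            f"need dt_bd < {max_stable_dt(k_a, D):.3e}"
        )
    if initial_bound < 0 or initial_bound > n_particles:
        raise ValueError("initial_bound out of range")
    n_free0 = n_particles - initial_bound
    pos = np.empty(max(n_particles, 1), dtype=np.float64)
    if initial_positions is not None:
        initial_positions = np.asarray(initial_positions, dtype=float)
        if len(initial_positions) != n_free0:
            raise ValueError("initial_positions length must equal free-particle count")
        pos[:n_free0] = initial_positions
    else:
        pos[:n_free0] = L0 + (R - L0) * rng.random(n_free0)
    n_steps = int(round(t_final / dt_bd))
    if n_particles == 0 or n_steps == 0:
        return BDEnsemble(pos[:n_free0].copy(), initial_bound, D, k_a, k_d, v, R, L0, 0.0)
    n_free, n_bound, L = bd_kernel(
        pos, n_free0, initial_bound, float(L0), float(R), float(D),
        float(k_a), float(k_d), float(v), float(dt_bd), n_steps, rng,
    )
    return BDEnsemble(
        free_positions=np.sort(pos[:n_free]).copy(),
        bound_count=int(n_bound),
        D=D, k_a=k_a, k_d=k_d, v=v, R=R, L=float(L), t=n_steps * dt_bd,
    )
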