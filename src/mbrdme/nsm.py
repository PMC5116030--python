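"""Reaction networks and exact RDME simulation via the Next Subvolume Method.

The RDME treats each voxel as locally well-mixed: chemical reactions fire
inside voxels with mass-action propensities, and diffusion is a Markov jump
process between neighboring voxels with the propensities assembled in
:mod:`mbrdme.mesh`.  ``nsm_run`` generates a statistically exact realization
of that Markov process, using a per-voxel next-event-time indexed binary
min-heap (Next Reaction Method across voxels, Direct Method within a voxel).
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import _kernels
from .mesh import JumpMatrix, Mesh, assemble_jump_rates


class UnsupportedReactionError(ValueError):
    pass


class InvalidModelError(ValueError):
    pass


@dataclass(frozen=True)
class Species:
    """A chemical species with an isotropic diffusion constant (μm²/s).

    ``subdomain_restriction`` confines both the species' copies and its
    diffusion to voxels carrying that label (e.g. ``"boundary"`` for
    membrane-bound proteins).
    """

    name: str
    diffusion_constant: float = 0.0
    subdomain_restriction: str = "all"

    def __post_init__(self):
        if self.diffusion_constant < 0:
            raise ValueError(f"diffusion constant of {self.name} must be >= 0")


@dataclass(frozen=True)
class Reaction:
    """A mass-action reaction of total reactant order <= 2.

    ``rate_constant`` units: 1/s (zeroth/unimolecular as written), μm³/s for
    bimolecular channels.  ``rate_hook(mesh, voxel)`` is an optional
    geometry-dependent multiplier evaluated when propensities are (re)built —
    e.g. ``1/h`` for a mesoscopic surface-binding rate on a 1D mesh.
    """

    reactants: dict[str, int]
    products: dict[str, int]
    rate_constant: float
    subdomain: str = "all"
    rate_hook: Callable[[Mesh, int], float] | None = None
    name: str = ""

    @property
    def order(self) -> int:
        return sum(self.reactants.values())

    def __post_init__(self):
        if any(v < 0 for v in {**self.reactants, **self.products}.values()):
            raise InvalidModelError("stoichiometry entries must be nonnegative")
        if self.order > 2:
            raise UnsupportedReactionError(
                f"reaction order {self.order} > 2 is not supported"
            )
        if self.rate_constant < 0:
            raise InvalidModelError("rate constant must be >= 0")


@dataclass
class ReactionNetwork:
    species: list[Species]
    reactions: list[Reaction] = field(default_factory=list)

    def __post_init__(self):
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise InvalidModelError("species names must be unique")
        self._index = {n: i for i, n in enumerate(names)}
        for r in self.reactions:
            for n in {**r.reactants, **r.products}:
                if n not in self._index:
                    raise InvalidModelError(f"reaction references unknown species {n!r}")
            # a reaction may only create a subdomain-restricted species where
            # that species is allowed to live
            for n in r.products:
                restr = self.species[self._index[n]].subdomain_restriction
                if restr == "all":
                    continue
                fires_in_restr = r.subdomain == restr or any(
                    self.species[self._index[m]].subdomain_restriction == restr
                    for m in r.reactants
                )
                if not fires_in_restr:
                    raise InvalidModelError(
                        f"reaction {r.name or r.reactants} can produce {n!r} outside "
                        f"its {restr!r} restriction"
                    )

    @property
    def species_index(self) -> dict[str, int]:
        return dict(self._index)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def index(self, name: str) -> int:
        return self._index[name]


@dataclass
class SystemState:
    """K×S matrix of nonnegative integer copy numbers."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.ascontiguousarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a K x S matrix")
        if np.any(self.counts < 0):
            raise ValueError("copy numbers must be nonnegative")

    @classmethod
    def zeros(cls, mesh: Mesh, network: ReactionNetwork) -> "SystemState":
        return cls(np.zeros((mesh.n_voxels, network.n_species), dtype=np.int64))

    def totals(self) -> np.ndarray:
        """Per-species total copy number (column sums)."""
        return self.counts.sum(axis=0)

    def copy(self) -> "SystemState":
        return SystemState(self.counts.copy())

    def validate(self, mesh: Mesh, network: ReactionNetwork) -> None:
        if self.counts.shape != (mesh.n_voxels, network.n_species):
            raise ValueError("state shape does not match mesh/network")
        for s, spec in enumerate(network.species):
            if spec.subdomain_restriction == "all":
                continue
            allowed = np.zeros(mesh.n_voxels, dtype=bool)
            allowed[mesh.voxels_in(spec.subdomain_restriction)] = True
            if np.any(self.counts[~allowed, s] > 0):
                raise ValueError(
                    f"species {spec.name!r} has copies outside its "
                    f"{spec.subdomain_restriction!r} restriction"
                )


# ---------------------------------------------------------------------------
# random-number state


def make_rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(seed))


def get_rng_state(rng: np.random.Generator):
    """Snapshot the generator state (cheap, serializable)."""
    return _copy.deepcopy(rng.bit_generator.state)


def set_rng_state(rng: np.random.Generator, state) -> None:
    rng.bit_generator.state = _copy.deepcopy(state)


# ---------------------------------------------------------------------------
# propensities


def propensity(
    reaction: Reaction,
    voxel_counts,
    voxel_volume: float,
    species_order: Sequence[str] | None = None,
    voxel_label: str = "all",
) -> float:
    """Mass-action propensity (1/s) of ``reaction`` in a single voxel.

    ``voxel_counts`` may be a mapping name→count or a vector ordered by
    ``species_order``.  Returns 0 if the voxel's subdomain label is excluded
    by the reaction's restriction.
    """
    if voxel_volume <= 0:
        raise ValueError("voxel volume must be > 0")
    if isinstance(voxel_counts, dict):
        counts = voxel_counts
    else:
        if species_order is None:
            raise ValueError("species_order required for vector counts")
        counts = dict(zip(species_order, np.asarray(voxel_counts)))
    if any(c < 0 for c in counts.values()):
        raise ValueError("copy numbers must be >= 0")
    if reaction.subdomain != "all" and voxel_label not in ("all", reaction.subdomain):
        return 0.0
    k = reaction.rate_constant
    order = reaction.order
    if order == 0:
        return k * voxel_volume
    if order == 1:
        (name, _), = reaction.reactants.items()
        return k * counts[name]
    names = list(reaction.reactants.items())
    if len(names) == 2:
        (a, _), (b, _) = names
        return k * counts[a] * counts[b] / voxel_volume
    (a, _), = names  # homodimerization
    xa = counts[a]
    return k * xa * (xa - 1) / (2.0 * voxel_volume)


def build_jump_matrices(mesh: Mesh, network: ReactionNetwork) -> dict[str, JumpMatrix]:
    """Per-species diffusion jump matrices for the current mesh geometry."""
    return {
        s.name: assemble_jump_rates(mesh, s.diffusion_constant, s.subdomain_restriction)
        for s in network.species
    }


def _compile_arrays(mesh: Mesh, network: ReactionNetwork, jumps: dict[str, JumpMatrix]):
    """Flatten mesh/network/jump data into the kernel's array form."""
    K = mesh.n_voxels
    S = network.n_species
    M = len(network.reactions)

    dif_indptr = np.zeros((S, K + 1), dtype=np.int64)
    cols_parts, rates_parts = [], []
    offset = 0
    outrate = np.zeros((S, K))
    for s, spec in enumerate(network.species):
        csr = jumps[spec.name].rates.tocsr()
        if csr.shape != (K, K):
            raise ValueError(f"jump matrix for {spec.name!r} does not match mesh")
        dif_indptr[s] = csr.indptr.astype(np.int64) + offset
        cols_parts.append(csr.indices.astype(np.int64))
        rates_parts.append(csr.data.astype(np.float64))
        outrate[s] = jumps[spec.name].out_rates
        offset += csr.nnz
    dif_cols = np.concatenate(cols_parts) if offset else np.zeros(0, dtype=np.int64)
    dif_rates = np.concatenate(rates_parts) if offset else np.zeros(0)

    r_order = np.zeros(M, dtype=np.int64)
    r_sp1 = np.zeros(M, dtype=np.int64)
    r_sp2 = np.zeros(M, dtype=np.int64)
    r_ratec = np.zeros((M, K))
    r_net = np.zeros((M, S), dtype=np.int64)
    for m, r in enumerate(network.reactions):
        idx = network.species_index
        for n, c in r.reactants.items():
            r_net[m, idx[n]] -= c
        for n, c in r.products.items():
            r_net[m, idx[n]] += c
        items = list(r.reactants.items())
        if r.order == 0:
            r_order[m] = _kernels.ORDER_ZERO
        elif r.order == 1:
            r_order[m] = _kernels.ORDER_UNI
            r_sp1[m] = idx[items[0][0]]
        elif len(items) == 2:
            r_order[m] = _kernels.ORDER_BI
            r_sp1[m] = idx[items[0][0]]
            r_sp2[m] = idx[items[1][0]]
        else:
            r_order[m] = _kernels.ORDER_DIMER
            r_sp1[m] = idx[items[0][0]]
        admissible = np.zeros(K, dtype=bool)
        admissible[mesh.voxels_in(r.subdomain)] = True
        for i in range(K):
            if not admissible[i]:
                continue
            mult = r.rate_hook(mesh, i) if r.rate_hook is not None else 1.0
            r_ratec[m, i] = r.rate_constant * mult
    vol = mesh.voxel_volumes.astype(np.float64)
    return vol, dif_indptr, dif_cols, dif_rates, outrate, r_order, r_sp1, r_sp2, r_ratec, r_net


def nsm_run(
    state: SystemState,
    mesh: Mesh,
    jumps: dict[str, JumpMatrix],
    network: ReactionNetwork,
    sample_times: Sequence[float],
    rng: np.random.Generator,
    t0: float = 0.0,
) -> list[SystemState]:
    """Simulate the RDME exactly from ``t0``, recording at ``sample_times``.

    Sampling is passive: recording intermediate states does not perturb the
    event sequence, so adding sample times leaves the final state unchanged
    for a fixed generator state.  The generator advances in place; snapshot it
    with :func:`get_rng_state` if replay is needed.
    """
    ts = np.asarray(sample_times, dtype=np.float64)
    if ts.ndim != 1 or len(ts) == 0:
        raise ValueError("sample_times must be a nonempty 1D sequence")
    if np.any(np.diff(ts) <= 0):
        raise ValueError("sample_times must be strictly increasing")
    if ts[0] < t0:
        raise ValueError("sample_times must be >= the current time")
    arrays = _compile_arrays(mesh, network, jumps)
    x = state.counts.copy()
    out = np.empty((len(ts), mesh.n_voxels, network.n_species), dtype=np.int64)
    _kernels.nsm_kernel(x, float(t0), ts, out, *arrays, rng)
    return [SystemState(out[k].copy()) for k in range(len(ts))]
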