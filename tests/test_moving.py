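"""Operator-splitting drivers: fixed step, adaptive rejection control,
harmonic velocity extension."""

import numpy as np
import pytest

from mbrdme import (
    ReactionNetwork,
    Species,
    SplitConfig,
    SystemState,
    build_ball_mesh,
    build_interval_mesh,
    build_jump_matrices,
    extend_velocity_to_interior,
    make_example1,
    make_rng,
    nsm_run,
    run_adaptive,
    run_fixed,
)


def _left_end_field(speed):
    def field(history, mesh, t):
        x = mesh.vertex_coords[:, 0]
        lo, hi = x.min(), x.max()
        v = np.zeros_like(mesh.vertex_coords)
        v[:, 0] = -speed * (hi - x) / (hi - lo)
        return v

    return field


def _zero_field(history, mesh, t):
    return np.zeros_like(mesh.vertex_coords)


class TestRunFixed:
    def test_zero_velocity_meshes_identical_and_conserving(self):
        mesh, net, init, _ = make_example1(10, k_a=0.0, v=0.0)
        cfg = SplitConfig(tau_split=0.1, t_final=0.5, seed=8)
        traj = run_fixed(mesh, init(2000), net, _zero_field, cfg)
        assert traj.aborted is None
        for m in traj.meshes:
            assert np.allclose(m.vertex_coords, mesh.vertex_coords)
        for s in traj.states:
            assert s.totals()[0] == 2000  # diffusion-only: exact conservation

    def test_constant_end_speed_final_endpoint(self):
        mesh, net, init, vel = make_example1(20, v=0.5)
        cfg = SplitConfig(tau_split=0.01, t_final=1.0, seed=2)
        traj = run_fixed(mesh, init(500, make_rng(2)), net, vel, cfg)
        left = traj.final_mesh.vertex_coords[:, 0].min()
        assert left == pytest.approx(-0.5, abs=0.01)  # within one Euler step
        assert [s.totals().sum() for s in traj.states] == [500] * len(traj.states)

    def test_static_domain_equivalence_with_plain_nsm(self):
        """With zero velocity the split driver's final-state distribution
        matches a single static NSM run (two-sample KS on the voxel-0
        marginal over replicates)."""
        from scipy.stats import ks_2samp

        mesh = build_interval_mesh(0, 1, 2)
        net = ReactionNetwork([Species("A", 1.0)])
        jumps = build_jump_matrices(mesh, net)
        counts0 = np.array([[50], [0]], dtype=np.int64)
        n_rep = 500
        split_final, plain_final = [], []
        rng = make_rng(31)
        for rep in range(n_rep):
            cfg = SplitConfig(tau_split=0.1, t_final=0.4, seed=10_000 + rep)
            traj = run_fixed(mesh, SystemState(counts0), net, _zero_field, cfg)
            split_final.append(traj.final_state.counts[0, 0])
            plain_final.append(
                nsm_run(SystemState(counts0), mesh, jumps, net, [0.4], rng)[0].counts[0, 0]
            )
        assert ks_2samp(split_final, plain_final).pvalue > 0.01

    def test_quality_abort_returns_partial_trajectory(self):
        # a collapsing interval must abort once a voxel inverts
        mesh, net, init, _ = make_example1(4, k_a=0.0, v=0.0)

        def crush(history, m, t):
            v = np.zeros_like(m.vertex_coords)
            v[0, 0] = 10.0  # left vertex sweeps right through its neighbors
            return v

        cfg = SplitConfig(tau_split=0.05, t_final=1.0, seed=0)
        traj = run_fixed(mesh, init(10), net, crush, cfg)
        assert traj.aborted is not None
        assert len(traj.times) >= 1


class TestRunAdaptive:
    def _inert(self, n_vox=4):
        mesh = build_interval_mesh(0, 1, n_vox)
        net = ReactionNetwork([Species("A", 0.0)])
        state = SystemState(np.zeros((n_vox, 1), dtype=np.int64))
        return mesh, net, state

    def test_zero_velocity_no_rejections(self):
        mesh, net, state = self._inert()
        cfg = SplitConfig(tau_split=0.1, t_final=1.0, seed=1, d_max=0.05)
        traj = run_adaptive(mesh, state, net, _zero_field, cfg)
        assert traj.aborted is None
        assert sum(traj.rejections) == 0
        assert len(traj.times) - 1 == 10  # ceil(t_final / tau_split) steps
        assert all(tau == pytest.approx(0.1) for tau in traj.taus[1:])

    def test_halving_arithmetic_and_displacement_bound(self):
        # ||v||inf * tau_split = 3 d_max: accept only after tau -> tau_split/4
        mesh, net, state = self._inert()
        speed = 1.0
        tau_split = 0.1
        d_max = speed * tau_split / 3.0
        cfg = SplitConfig(tau_split=tau_split, t_final=1.0, seed=3, d_max=d_max)
        traj = run_adaptive(mesh, state, net, _left_end_field(speed), cfg)
        assert traj.aborted is None
        assert traj.rejections[1] == 2
        assert traj.taus[1] == pytest.approx(tau_split / 4)
        for tau in traj.taus[1:]:
            assert speed * tau <= d_max + 1e-12

    def test_tau_doubles_after_clean_acceptance(self):
        # fast boundary early, still later: tau halves, then ramps back up
        mesh, net, state = self._inert()

        def gusty(history, m, t):
            return _left_end_field(1.0 if t <= 0.3 else 0.0)(history, m, t)

        cfg = SplitConfig(tau_split=0.1, t_final=1.0, seed=5, d_max=0.1 / 3)
        traj = run_adaptive(mesh, state, net, gusty, cfg)
        taus = traj.taus[1:]
        ratios = [taus[i + 1] / taus[i] for i in range(len(taus) - 1)]
        assert any(r == pytest.approx(2.0) for r in ratios)
        assert max(taus) == pytest.approx(0.1)  # doubling capped at tau_split

    def test_replay_determinism_through_rejections(self):
        mesh, net, _ = self._inert()
        net = ReactionNetwork([Species("A", 0.5)])
        counts = np.zeros((4, 1), dtype=np.int64)
        counts[2, 0] = 200
        cfg = SplitConfig(tau_split=0.1, t_final=1.0, seed=9, d_max=0.1 / 3)
        runs = [
            run_adaptive(mesh, SystemState(counts), net, _left_end_field(1.0), cfg)
            for _ in range(2)
        ]
        assert runs[0].times == runs[1].times
        assert runs[0].taus == runs[1].taus
        assert runs[0].rejections == runs[1].rejections
        for a, b in zip(runs[0].states, runs[1].states):
            assert np.array_equal(a.counts, b.counts)
        for a, b in zip(runs[0].meshes, runs[1].meshes):
            assert np.array_equal(a.vertex_coords, b.vertex_coords)

    def test_more_than_three_halvings_replays_biochemistry(self):
        # ||v||inf tau_split = 20 d_max needs 5 halvings -> NSM replay path
        mesh, net, _ = self._inert()
        net = ReactionNetwork([Species("A", 0.5)])
        counts = np.full((4, 1), 100, dtype=np.int64)
        cfg = SplitConfig(tau_split=0.1, t_final=0.3, seed=21, d_max=1.0 * 0.1 / 20)
        traj = run_adaptive(mesh, SystemState(counts), net, _left_end_field(1.0), cfg)
        assert traj.aborted is None
        assert traj.rejections[1] == 5
        assert traj.taus[1] == pytest.approx(0.1 / 32)
        assert all(1.0 * tau <= cfg.d_max + 1e-12 for tau in traj.taus[1:])
        for s in traj.states:
            assert s.totals()[0] == 400

    def test_tau_underflow_aborts(self):
        mesh, net, state = self._inert()
        cfg = SplitConfig(
            tau_split=0.1, t_final=1.0, seed=2, d_max=1e-9, tau_floor_factor=2.0**-6
        )
        traj = run_adaptive(mesh, state, net, _left_end_field(1.0), cfg)
        assert traj.aborted is not None
        assert "underflow" in traj.aborted

    def test_requires_d_max(self):
        mesh, net, state = self._inert()
        cfg = SplitConfig(tau_split=0.1, t_final=1.0, seed=2)
        with pytest.raises(ValueError):
            run_adaptive(mesh, state, net, _zero_field, cfg)


def test_splitting_error_decreases_with_tau(example1_sweep):
    """KS error against the BD oracle trends downward across the whole
    τ_split ladder {0.2, 0.1, 0.05, 0.01} at v = 0.5 (monotone trend:
    positive regression slope of per-replicate KS on τ_split)."""
    from scipy.stats import linregress

    fast = example1_sweep[example1_sweep.v == 0.5]
    fit = linregress(fast.dt_split, fast.ks)
    assert fit.slope > 0
    assert fit.pvalue / 2 < 0.05  # one-sided
    means = fast.groupby("dt_split").ks.mean()
    assert means[0.01] < means[0.2]


class TestExtendVelocity:
    def test_constant_boundary_field_extends_to_constant(self, unit_ball_res2):
        nb = len(unit_ball_res2.boundary_vertices)
        bvel = np.tile([0.2, -0.1, 0.05], (nb, 1))
        full = extend_velocity_to_interior(unit_ball_res2, bvel)
        assert np.allclose(full, [0.2, -0.1, 0.05], atol=1e-9)

    def test_zero_boundary_field_is_zero(self, unit_ball_res2):
        nb = len(unit_ball_res2.boundary_vertices)
        full = extend_velocity_to_interior(unit_ball_res2, np.zeros((nb, 3)))
        assert np.allclose(full, 0.0)

    def test_radial_boundary_field_stays_radial(self):
        mesh = build_ball_mesh(1.0, 2)
        bverts = mesh.boundary_vertices
        r_hat = mesh.vertex_coords[bverts]
        r_hat /= np.linalg.norm(r_hat, axis=1)[:, None]
        full = extend_velocity_to_interior(mesh, 0.3 * r_hat)
        # interior vectors should be (close to) radial: small tangential part
        interior = np.setdiff1d(np.arange(mesh.n_vertices), bverts)
        pts = mesh.vertex_coords[interior]
        radii = np.linalg.norm(pts, axis=1)
        keep = radii > 0.3  # skip near-center vertices where direction is ill-defined
        u = pts[keep] / radii[keep][:, None]
        v = full[interior][keep]
        radial = np.einsum("ij,ij->i", v, u)
        tangential = np.linalg.norm(v - radial[:, None] * u, axis=1)
        # discretization tolerance of the graph-Laplacian extension
        assert np.all(tangential <= 0.25 * np.abs(radial) + 1e-9)
        assert np.median(tangential / np.abs(radial)) < 0.1
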