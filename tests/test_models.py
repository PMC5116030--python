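"""Model builders, the critical-radius formula, velocity-field constructors
and the mean-field oracle."""

import numpy as np
import pytest

from mbrdme import (
    PolarizationParams,
    TipGrowthParams,
    build_jump_matrices,
    critical_radius,
    make_example1,
    make_polarization_model,
    make_rng,
    meanfield_steady_state,
    nsm_run,
    tip_growth_velocity_field_for,
    radial_velocity_field,
)
from mbrdme.mesh import move_mesh
from mbrdme.models import membrane_volume
from mbrdme.moving import SplitConfig, run_fixed
from mbrdme.nsm import InvalidModelError, SystemState


class TestExample1:
    def test_binding_propensity_uses_mesoscopic_rate(self):
        mesh, net, init, _ = make_example1(20, k_a=50.0, k_d=1.0)
        from mbrdme.nsm import _compile_arrays

        jumps = build_jump_matrices(mesh, net)
        ratec = _compile_arrays(mesh, net, jumps)[8]
        bind = [r.name for r in net.reactions].index("bind")
        assert ratec[bind, 0] == pytest.approx(1000.0)  # k_a / h with h = 0.05
        assert np.all(ratec[bind, 1:] == 0.0)  # binding only at the reactive end

    def test_voxel_width_from_count(self):
        mesh, _, _, _ = make_example1(5)
        assert np.allclose(mesh.voxel_volumes, 0.2)

    def test_static_equilibrium_bound_fraction(self):
        # v = 0: flux balance gives bound fraction k_a/(k_a + k_d l) = 50/51;
        # capture of free molecules is diffusion-limited (relaxation ~0.5 s),
        # so replicates start at the equilibrium partition and must stay there
        mesh, net, init, vel = make_example1(20, v=0.0)
        jumps = build_jump_matrices(mesh, net)
        rng = make_rng(20)
        p = 50.0 / 51.0
        fracs = []
        n = 5000
        for _ in range(8):
            counts = init(n, rng).counts
            nb0 = rng.binomial(int(counts[:, 0].sum()), p)
            counts[0, 1] = nb0
            counts[:, 0] = rng.multinomial(n - nb0, np.full(20, 1 / 20))
            out = nsm_run(SystemState(counts), mesh, jumps, net, [1.0], rng)[-1]
            fracs.append(out.counts[:, net.index("S_b")].sum() / n)
        sem = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert np.mean(fracs) == pytest.approx(p, abs=3 * max(sem, 1e-4))

    def test_invalid_voxel_count(self):
        with pytest.raises(ValueError):
            make_example1(0)


class TestCriticalRadius:
    def test_printed_value(self):
        assert critical_radius(1000, 0.9) == pytest.approx(6.425, abs=5e-4)

    def test_cube_root_scaling(self):
        assert critical_radius(2000, 0.9) == pytest.approx(
            critical_radius(1000, 0.9) * 2 ** (1 / 3)
        )

    def test_zero_molecules(self):
        assert critical_radius(0, 0.9) == 0.0

    def test_zero_ratio_rejected(self):
        with pytest.raises(ValueError):
            critical_radius(1000, 0.0)


class TestPolarizationModel:
    def test_total_count_conserved(self):
        params = PolarizationParams(radius=2.0, N_total=300)
        mesh, net, init = make_polarization_model(params, 1)
        jumps = build_jump_matrices(mesh, net)
        rng = make_rng(2)
        out = nsm_run(init(rng), mesh, jumps, net, [1.0, 5.0], rng)
        for s in out:
            assert s.counts.sum() == 300

    def test_one_way_decay_without_feedback_or_attachment(self):
        params = PolarizationParams(radius=2.0, N_total=200, k_on=0.0, k_fb=0.0)
        mesh, net, init = make_polarization_model(params, 1)
        jumps = build_jump_matrices(mesh, net)
        rng = make_rng(3)
        counts = np.zeros((mesh.n_voxels, 2), dtype=np.int64)
        counts[mesh.voxels_in("boundary")[:10], 1] = 20  # start all on the membrane
        out = nsm_run(SystemState(counts), mesh, jumps, net, [30.0], rng)[-1]
        assert out.counts[:, net.index("Cdc42m")].sum() == 0
        assert out.counts[:, net.index("Cdc42c")].sum() == 200

    def test_no_feedback_equilibrium_matches_two_state_balance(self):
        # k_fb = 0: membrane/cytosol partition set by the restricted attachment
        params = PolarizationParams(radius=2.0, N_total=2000, k_on=2.0, k_off=1.0, k_fb=0.0)
        mesh, net, init = make_polarization_model(params, 2)
        v_m, v = membrane_volume(mesh), mesh.total_volume()
        k_eff = params.k_on * v_m / v
        expected_m = 2000 * k_eff / (k_eff + params.k_off)
        ss = meanfield_steady_state(net, v, v_m, 2000)
        assert ss["Cdc42m"] == pytest.approx(expected_m, rel=1e-6)
        jumps = build_jump_matrices(mesh, net)
        rng = make_rng(4)
        sims = [
            nsm_run(init(rng), mesh, jumps, net, [15.0], rng)[-1].counts[:, 1].sum()
            for _ in range(6)
        ]
        sem = np.std(sims, ddof=1) / np.sqrt(len(sims))
        assert np.mean(sims) == pytest.approx(expected_m, abs=3 * max(sem, 1.0))


class TestVelocityFields:
    def test_radial_expansion_rate(self):
        from mbrdme.mesh import build_ball_mesh

        mesh = build_ball_mesh(6.0, 1)
        field = radial_velocity_field(0.01)
        for _ in range(10):
            v = field([], mesh, 0.0)
            mesh = move_mesh(mesh, v, 10.0)
        r = np.linalg.norm(mesh.vertex_coords, axis=1).max()
        assert r == pytest.approx(7.0, rel=1e-9)  # 6 + 0.01*100

    def test_zero_rate_static(self, unit_ball_res2):
        v = radial_velocity_field(0.0)([], unit_ball_res2, 0.0)
        assert np.allclose(v, 0.0)

    def test_negative_rate_contracts(self):
        from mbrdme.mesh import build_ball_mesh

        mesh = build_ball_mesh(2.0, 1)
        v = radial_velocity_field(-0.1)([], mesh, 0.0)
        moved = move_mesh(mesh, v, 1.0)
        assert moved.total_volume() < mesh.total_volume()
        assert np.all(moved.voxel_volumes > 0)

    def test_tip_growth_peak_speed_and_decay(self):
        params = PolarizationParams(radius=2.0, N_total=100)
        mesh, net, init = make_polarization_model(params, 1)
        tg = TipGrowthParams("Cdc42m", v_max=0.02, sigma=0.5)
        field = tip_growth_velocity_field_for(net, tg)
        boundary = mesh.voxels_in("boundary")
        counts = np.zeros((mesh.n_voxels, 2), dtype=np.int64)
        peak = boundary[5]
        counts[peak, 1] = 100
        v = field([(0.0, SystemState(counts))], mesh, 0.0)
        speeds = np.linalg.norm(v, axis=1)
        assert speeds[peak] == pytest.approx(0.02, rel=1e-6)
        d = np.linalg.norm(mesh.vertex_coords[boundary] - mesh.voxel_centers[peak], axis=1)
        expected = 0.02 * np.exp(-(d**2) / (2 * 0.5**2))
        assert np.allclose(speeds[boundary], expected, rtol=1e-6)

    def test_tip_growth_sigma_infinity_is_rigid_translation(self):
        params = PolarizationParams(radius=2.0, N_total=100)
        mesh, net, init = make_polarization_model(params, 1)
        field = tip_growth_velocity_field_for(net, TipGrowthParams("Cdc42m", 0.01, sigma=1e9))
        counts = np.zeros((mesh.n_voxels, 2), dtype=np.int64)
        counts[mesh.voxels_in("boundary")[0], 1] = 10
        v = field([(0.0, SystemState(counts))], mesh, 0.0)
        assert np.allclose(v, v[0], atol=1e-9)
        assert np.linalg.norm(v[0]) == pytest.approx(0.01, rel=1e-6)

    def test_tip_growth_zero_molecules_zero_field(self):
        params = PolarizationParams(radius=2.0, N_total=0)
        mesh, net, init = make_polarization_model(params, 1)
        field = tip_growth_velocity_field_for(net, TipGrowthParams("Cdc42m", 0.01, 1.0))
        v = field([(0.0, SystemState(np.zeros((mesh.n_voxels, 2), dtype=np.int64)))], mesh, 0.0)
        assert np.allclose(v, 0.0)

    def test_tip_growth_requires_membrane_species(self):
        mesh, net, init, _ = make_example1(5)
        with pytest.raises(InvalidModelError):
            tip_growth_velocity_field_for(net, TipGrowthParams("S", 0.01, 1.0))


class TestMeanfield:
    def test_all_cytosolic_without_channels_to_membrane(self):
        params = PolarizationParams(radius=3.0, k_on=0.0, k_fb=0.0)
        mesh, net, _ = make_polarization_model(params, 1)
        ss = meanfield_steady_state(net, mesh.total_volume(), membrane_volume(mesh), 500)
        assert ss["Cdc42c"] == pytest.approx(500.0, abs=1e-6)
        assert ss["Cdc42m"] == pytest.approx(0.0, abs=1e-6)

    def test_unrestricted_two_state_closed_form(self):
        # membrane volume == total volume: the classic k_on/(k_on+k_off) split
        params = PolarizationParams(radius=3.0, k_on=2.0, k_off=3.0, k_fb=0.0)
        mesh, net, _ = make_polarization_model(params, 1)
        v = mesh.total_volume()
        ss = meanfield_steady_state(net, v, v, 1000)
        assert ss["Cdc42m"] == pytest.approx(1000 * 2.0 / 5.0, rel=1e-8)

    def test_total_conserved(self):
        params = PolarizationParams(radius=4.0)
        mesh, net, _ = make_polarization_model(params, 1)
        ss = meanfield_steady_state(net, mesh.total_volume(), membrane_volume(mesh), 1000)
        assert ss["Cdc42c"] + ss["Cdc42m"] == pytest.approx(1000.0, rel=1e-9)
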