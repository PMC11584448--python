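"""Gait events, kinematics extraction, regional stresses and sweeps."""

import numpy as np
import pytest

import breastfem as bf
from breastfem.experiments import (EVENT_NAMES, GaitEvents, default_regions,
                                   representative_nodes)
from breastfem.fesolve import SimulationResult


def fake_result(mesh, n_frames=5, translation=None, vm_value=0.0):
    """Synthetic SimulationResult: optional rigid translation history and a
    uniform von Mises field."""
    n = mesh.n_nodes
    U = np.zeros((n_frames, n, 3))
    if translation is not None:
        for k in range(n_frames):
            U[k] += np.asarray(translation) * k
    return SimulationResult(
        times=0.005 * np.arange(n_frames),
        nodal_displacement=U,
        nodal_velocity=np.zeros_like(U),
        nodal_acceleration=np.zeros_like(U),
        element_von_mises=np.full((n_frames, mesh.n_tets), vm_value),
        convergence_log=[])


class TestGaitEvents:
    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            GaitEvents(t1=0.2, t2=0.1, t3=0.3, t4=0.4)

    def test_noiseless_sinusoid_extrema(self):
        T = 0.38
        tr = bf.build_synthetic_gait(duration=2 * T, half_cycle=T,
                                     noise_sd=0.0)
        ev = bf.detect_events(tr, half_cycle=T)
        assert ev.t2 == pytest.approx(T / 4, abs=1.0 / 120.0)
        assert ev.t4 == pytest.approx(3 * T / 4, abs=1.0 / 120.0)
        assert ev.t1 < ev.t2 < ev.t3 < ev.t4

    def test_noise_shifts_events_at_most_two_samples(self):
        T = 0.38
        clean = bf.detect_events(
            bf.build_synthetic_gait(duration=2 * T, half_cycle=T,
                                    noise_sd=0.0), half_cycle=T)
        noisy_tr = bf.butterworth_zero_lag(bf.build_synthetic_gait(
            duration=2 * T, half_cycle=T, noise_sd=0.5, seed=11))
        noisy = bf.detect_events(noisy_tr, half_cycle=T)
        dt = 1.0 / 120.0
        assert abs(noisy.t2 - clean.t2) <= 2 * dt
        assert abs(noisy.t4 - clean.t4) <= 2 * dt

    def test_requested_half_cycle_window(self):
        T = 0.38
        tr = bf.build_synthetic_gait(duration=3 * T, half_cycle=T,
                                     noise_sd=0.0)
        ev0 = bf.detect_events(tr, half_cycle=T, index=0)
        ev1 = bf.detect_events(tr, half_cycle=T, index=1)
        assert ev0.t2 < T < ev1.t1 + 1e-9
        assert ev1.t2 == pytest.approx(ev0.t2 + T, abs=1.0 / 120.0)

    def test_flat_signal_rejected(self):
        tr = bf.build_synthetic_gait(duration=0.5, amp_y=0.0, amp_x=0.0,
                                     noise_sd=0.0)
        with pytest.raises(ValueError, match="flat"):
            bf.detect_events(tr, half_cycle=0.38)

    def test_period_estimated_when_omitted(self):
        tr = bf.build_synthetic_gait(duration=3.04, half_cycle=0.38,
                                     noise_sd=0.0)
        ev = bf.detect_events(tr)
        assert ev.t2 == pytest.approx(0.095, abs=2.0 / 120.0)


class TestKinematics:
    def test_representative_nodes_cover_components(self, default_mesh):
        reps = representative_nodes(default_mesh)
        assert set(reps) == {"nipple", "clavicle", "ligament", "gland",
                             "pectoralis"}
        driven = set(default_mesh.node_sets["torso_base"])
        for comp in ("ligament", "gland", "pectoralis", "nipple"):
            assert reps[comp] not in driven

    def test_pure_translation_identical_displacement(self, default_mesh):
        res = fake_result(default_mesh, translation=(1.0, -2.0, 0.5))
        kin = bf.extract_component_kinematics(res, default_mesh)
        peaks = {c: k["peak_displacement"] for c, k in kin.items()}
        ref = peaks["nipple"]
        assert all(p == pytest.approx(ref, rel=1e-12) for p in peaks.values())

    def test_static_history_zero_acceleration(self, default_mesh):
        res = fake_result(default_mesh)
        kin = bf.extract_component_kinematics(res, default_mesh)
        assert all(k["peak_acceleration"] == 0.0 for k in kin.values())


class TestRegionalStress:
    def test_default_regions_present_and_nonempty(self, default_mesh):
        regions = default_regions(default_mesh)
        for k in range(1, 9):
            assert f"L{k}" in regions and regions[f"L{k}"].size > 0
        for name in ("lig_anterior", "lig_posterior", "pec_anterior",
                     "pec_posterior", "gland_front", "gland_rear",
                     "gland_top", "gland_bottom", "adipose_near_gland"):
            assert name in regions and regions[name].size > 0

    def test_zero_stress_gives_zero_means(self, default_mesh):
        res = fake_result(default_mesh, vm_value=0.0)
        summary = bf.regional_stress_summary(res, default_mesh)
        assert all(v["peak_value"] == 0.0 for v in summary.values())

    def test_uniform_field_mean_equals_field(self, default_mesh):
        s = 3.25
        res = fake_result(default_mesh, vm_value=s)
        summary = bf.regional_stress_summary(res, default_mesh)
        for v in summary.values():
            assert v["peak_value"] == pytest.approx(s, rel=1e-12)

    def test_empty_region_rejected(self, default_mesh):
        res = fake_result(default_mesh)
        with pytest.raises(ValueError, match="empty"):
            bf.regional_stress_summary(res, default_mesh,
                                       regions={"nothing": np.empty(0, int)})


class TestStiffnessSweep:
    def test_default_grids_match_experiment_design(self):
        from breastfem.experiments import GLAND_E_GRID, LIGAMENT_E_GRID
        assert GLAND_E_GRID == (5.0, 7.5, 10.0, 12.5, 15.0)
        assert LIGAMENT_E_GRID == (80.0, 100.0, 120.0, 140.0, 160.0)

    def test_unknown_component_rejected(self, coarse_mesh, materials):
        traj = bf.build_synthetic_gait(duration=0.4, noise_sd=0.0)
        cfg = bf.SweepConfig(mesh=coarse_mesh, materials=materials,
                             trajectory=traj, n_steps=4)
        with pytest.raises(ValueError):
            bf.stiffness_sweep(cfg, "skin")

    def test_nonpositive_modulus_rejected(self, coarse_mesh, materials):
        traj = bf.build_synthetic_gait(duration=0.4, noise_sd=0.0)
        cfg = bf.SweepConfig(mesh=coarse_mesh, materials=materials,
                             trajectory=traj, n_steps=4)
        with pytest.raises(ValueError):
            bf.stiffness_sweep(cfg, "gland", E_values=[-1.0, 5.0])

    def test_sweep_deterministic_and_tidy_output(self, coarse_mesh,
                                                 materials):
        traj = bf.build_synthetic_gait(duration=0.4, amp_y=10.0, amp_x=4.0,
                                       noise_sd=0.0)
        cfg = bf.SweepConfig(mesh=coarse_mesh, materials=materials,
                             trajectory=traj, n_steps=8, half_cycle=0.38)
        s1 = bf.stiffness_sweep(cfg, "gland", E_values=[5.0, 15.0])
        s2 = bf.stiffness_sweep(cfg, "gland", E_values=[5.0, 15.0])
        assert np.array_equal(s1.displacement, s2.displacement)
        df = s1.to_frame()
        assert list(df.columns) == ["E_kPa", "event", "peak_disp_mm"]
        assert len(df) == 2 * len(EVENT_NAMES)
        fit = s1.fit_summary()
        assert set(fit["slope_mm_per_kPa"]) == set(EVENT_NAMES)
        # r is NaN when the two-point response is flat; otherwise |r| <= 1
        assert all(np.isnan(r) or abs(r) <= 1.0 + 1e-12
                   for r in fit["pearson_r"].values())
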