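"""Generative models: Langevin rotation, Poisson stepping, benchmark data."""

import math

import numpy as np
import pytest

from archtorque import markers as mk
from archtorque import synthetic as syn
from archtorque.errors import ConfigError, ParameterError, StabilityError


def window_rate(times, angles):
    return abs(angles[-1] - angles[0]) / (2 * math.pi * (times[-1] - times[0]))


class TestModelA:
    def test_zero_temperature_rate_exact(self):
        """Noiseless limit: uniform rate exactly T_a/2π(γ+γ_a)."""
        motor = syn.MotorParams(torque_pn_nm=160.0, gamma_a_pn_nm_s=0.81)
        sim = syn.SimParams(duration_s=0.5, k_bt_pn_nm=0.0, seed=0)
        gamma = 0.206273  # 210-nm bead at R = 250 nm
        t, th = syn.simulate_angles(motor, gamma, sim)
        expected = syn.mean_rate_hz(motor, gamma)
        # exact over any window, not just end-to-end
        for a, b in [(0, len(t) - 1), (10, 60), (200, 900)]:
            assert window_rate(t[a:b], th[a:b]) == pytest.approx(
                expected, rel=1e-12)

    def test_direction_sign(self):
        sim = syn.SimParams(duration_s=0.1, k_bt_pn_nm=0.0)
        cw = syn.MotorParams(direction="CW")
        ccw = syn.MotorParams(direction="CCW")
        _, th_cw = syn.simulate_angles(cw, 1.0, sim)
        _, th_ccw = syn.simulate_angles(ccw, 1.0, sim)
        assert th_cw[-1] < 0 < th_ccw[-1]
        assert th_cw[-1] == pytest.approx(-th_ccw[-1], rel=1e-12)

    def test_rotational_diffusion_msd(self):
        """With T_a → (torque irrelevant at k_BT only) the angular MSD must
        grow as 2·(k_BT/γ_tot)·t; checked from 10⁵ increments."""
        motor = syn.MotorParams(torque_pn_nm=1e-9, gamma_a_pn_nm_s=0.0)
        sim = syn.SimParams(duration_s=50.0, dt_s=5e-4, seed=3, substeps=1)
        gamma = 2.0
        t, th = syn.simulate_angles(motor, gamma, sim)
        inc = np.diff(th)
        d_est = np.var(inc) / (2 * sim.dt_s)
        d_true = sim.k_bt_pn_nm / gamma
        assert d_est == pytest.approx(d_true, rel=0.05)

    def test_unstable_step_rejected(self):
        motor = syn.MotorParams(torque_pn_nm=1e6, gamma_a_pn_nm_s=0.01)
        sim = syn.SimParams(duration_s=0.1, substeps=1)
        with pytest.raises(StabilityError):
            syn.simulate_angles(motor, 0.0, sim)


class TestModelB:
    def test_no_load_limit(self):
        """γ → 0: mean rate converges to f_noload (3 SE over ≥1000 steps)."""
        f0 = 25.0
        motor = syn.MotorParams(torque_pn_nm=160.0, mode="model_B",
                                f_noload_hz=f0)
        # 20 s × 25 Hz × 6 steps/rev = 3000 steps
        sim = syn.SimParams(duration_s=20.0, seed=4)
        t, th = syn.simulate_angles(motor, 0.0, sim)
        n_steps = abs(th[-1]) / math.radians(60.0)
        assert n_steps > 1000
        se = f0 / math.sqrt(n_steps)  # exponential dwells: CV = 1 per step
        assert abs(window_rate(t, th) - f0) < 3 * se

    def test_mean_rate_formula(self):
        """Loaded stepping follows f = (1/f_noload + 2πγ/T_a)⁻¹."""
        motor = syn.MotorParams(torque_pn_nm=160.0, mode="model_B",
                                f_noload_hz=30.0)
        gamma = 2.0
        expected = syn.mean_rate_hz(motor, gamma)
        sim = syn.SimParams(duration_s=60.0, dt_s=1e-3, seed=5)
        t, th = syn.simulate_angles(motor, gamma, sim)
        assert window_rate(t, th) == pytest.approx(expected, rel=0.05)

    def test_requires_f_noload(self):
        with pytest.raises(ParameterError):
            syn.MotorParams(mode="model_B")


class TestTraceGeometry:
    def test_orbit_lies_on_specified_circle(self):
        plane = syn.PlaneSpec(theta_deg=35.0, phi_deg=120.0,
                              center_nm=(100.0, -50.0, 400.0))
        marker = mk.MarkerGeometry.sphere(210.0, 250.0)
        sim = syn.SimParams(duration_s=0.1, k_bt_pn_nm=0.0)
        traj = syn.simulate_rotation_trace(syn.MotorParams(), marker, plane,
                                           sim)
        center = np.array(plane.center_nm)
        radii = np.linalg.norm(traj.positions - center, axis=1)
        assert np.allclose(radii, 250.0, rtol=1e-9)
        # all points in the plane: zero component along the normal
        _, _, n = syn.plane_basis(35.0, 120.0)
        oop = (traj.positions - center) @ n
        assert np.max(np.abs(oop)) < 1e-6

    def test_tethered_cell_lever_arm(self):
        marker = mk.MarkerGeometry.tethered_cell(2500.0)
        sim = syn.SimParams(duration_s=4.0, k_bt_pn_nm=0.0)
        traj = syn.simulate_rotation_trace(syn.MotorParams(), marker,
                                           syn.PlaneSpec(), sim)
        radii = np.linalg.norm(traj.positions, axis=1)
        assert np.allclose(radii, 2500.0, rtol=1e-9)


class TestBenchmarkDataset:
    def test_default_class_counts(self):
        """Default study conditions: 32/31/26/12 markers per size class."""
        df = syn.build_benchmark_dataset(seed=0)
        spheres = df[df.kind == "sphere"]
        counts = spheres.groupby("diameter_nm").size()
        assert counts[210.0] == 32
        assert counts[490.0] == 31
        assert counts[1000.0] == 26
        assert (df.kind == "rod").sum() == 12
        assert list(df.columns) == syn.DATASET_COLUMNS

    def test_seed_reproducibility(self):
        a = syn.build_benchmark_dataset(seed=7)
        b = syn.build_benchmark_dataset(seed=7)
        assert a.equals(b)
        c = syn.build_benchmark_dataset(seed=8)
        assert not a.equals(c)

    def test_empty_class_list_rejected(self):
        with pytest.raises(ConfigError):
            syn.BenchmarkConfig(classes=[])

    def test_rates_scale_with_load(self):
        df = syn.build_benchmark_dataset(seed=1)
        means = df[df.kind == "sphere"].groupby("diameter_nm")["rate_hz"].mean()
        assert means[210.0] > means[490.0] > means[1000.0]
        assert df[df.kind == "rod"]["rate_hz"].mean() < means[1000.0]


class TestDualSpotRendering:
    def test_baseline_separation_at_reference_height(self):
        """z = 0 and no noise → separation equals the baseline exactly."""
        from archtorque.optics import OpticsParams
        from archtorque.tracking import frame_separation
        optics = OpticsParams()
        traj_pos = np.array([[0.0, 0.0, 0.0]])
        traj = _single_frame_traj(traj_pos)
        stack = syn.render_dual_image_stack(traj, optics, noise=False)
        sep = frame_separation(stack.frames[0], optics)
        assert sep == pytest.approx(optics.baseline_separation_nm, abs=0.05)

    def test_linear_axial_encoding(self):
        """+100 nm of z at gain 0.5 adds exactly 50 nm of separation."""
        from archtorque.optics import OpticsParams
        from archtorque.tracking import frame_separation
        optics = OpticsParams(axial_gain=0.5)
        s0 = frame_separation(syn.render_dual_image_stack(
            _single_frame_traj(np.array([[0.0, 0.0, 0.0]])), optics,
            noise=False).frames[0], optics)
        s1 = frame_separation(syn.render_dual_image_stack(
            _single_frame_traj(np.array([[0.0, 0.0, 100.0]])), optics,
            noise=False).frames[0], optics)
        assert s1 - s0 == pytest.approx(50.0, abs=0.1)

    def test_photon_counts_poisson(self):
        """Per-frame total photon count is Poisson: dispersion χ² test."""
        from scipy import stats
        from archtorque.optics import OpticsParams
        optics = OpticsParams(photons_per_spot=2000.0, read_noise_counts=0.0,
                              camera_offset_counts=0.0)
        n_frames = 400
        pos = np.zeros((n_frames, 3))
        traj = syn.Trajectory3D(times=np.arange(n_frames) * 5e-4,
                                positions=pos)
        stack = syn.render_dual_image_stack(traj, optics, seed=9)
        totals = stack.frames.sum(axis=(1, 2)).astype(float)
        mean = totals.mean()
        chi2 = (n_frames - 1) * totals.var(ddof=1) / mean
        lo, hi = stats.chi2.ppf([0.005, 0.995], df=n_frames - 1)
        assert lo < chi2 < hi

    def test_overlap_warning(self):
        from archtorque.optics import OpticsParams
        optics = OpticsParams(baseline_separation_nm=100.0, axial_gain=0.5)
        stack = syn.render_dual_image_stack(
            _single_frame_traj(np.array([[0.0, 0.0, 0.0]])), optics,
            noise=False)
        assert stack.meta["warnings"]

    def test_deterministic_under_seed(self):
        from archtorque.optics import OpticsParams
        optics = OpticsParams()
        traj = _single_frame_traj(np.array([[10.0, -20.0, 50.0]]))
        a = syn.render_dual_image_stack(traj, optics, seed=3)
        b = syn.render_dual_image_stack(traj, optics, seed=3)
        assert np.array_equal(a.frames, b.frames)


def _single_frame_traj(pos):
    from archtorque.trajectory import Trajectory3D
    return Trajectory3D(times=np.arange(len(pos)) * 5e-4, positions=pos)
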