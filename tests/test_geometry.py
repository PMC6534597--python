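"""Rotation-plane search, circle fit, rate estimation and trace QC."""

import math

import numpy as np
import pytest

from archtorque import geometry as geo
from archtorque import markers as mk
from archtorque import synthetic as syn
from archtorque.errors import GeometryError
from archtorque.trajectory import Trajectory3D


def circle_traj(theta=0.0, phi=0.0, radius=250.0, rate=21.8, n=2000,
                center=(0.0, 0.0, 0.0), noise=0.0, seed=0, phases=None):
    u, v, _ = syn.plane_basis(theta, phi)
    t = np.arange(n) * 5e-4
    ph = phases if phases is not None else 2 * np.pi * rate * t
    pos = (np.asarray(center, dtype=float)
           + radius * (np.cos(ph)[:, None] * u + np.sin(ph)[:, None] * v))
    if noise > 0:
        pos = pos + np.random.default_rng(seed).normal(0, noise, pos.shape)
    return Trajectory3D(times=t, positions=pos)


class TestFindRotationPlane:
    def test_untilted_circle(self):
        pf = geo.find_rotation_plane(circle_traj(theta=0.0))
        assert pf.theta_deg == pytest.approx(0.0, abs=0.1)
        assert pf.circularity_score < 1e-6

    def test_tilted_circle_recovery(self):
        """Noiseless circle tilted (35°, 120°): both angles within 0.1°."""
        pf = geo.find_rotation_plane(circle_traj(theta=35.0, phi=120.0))
        assert pf.theta_deg == pytest.approx(35.0, abs=0.1)
        assert pf.phi_deg == pytest.approx(120.0, abs=0.1)

    def test_rotation_equivariance(self):
        """Rotating the input rotates the fitted normal identically."""
        from scipy.spatial.transform import Rotation
        traj = circle_traj(theta=35.0, phi=120.0)
        rot = Rotation.from_euler("zyx", [25.0, 10.0, 5.0], degrees=True)
        rotated = Trajectory3D(times=traj.times,
                               positions=traj.positions @ rot.as_matrix().T)
        pf0 = geo.find_rotation_plane(traj)
        pf1 = geo.find_rotation_plane(rotated)
        n0, n1 = pf0.normal, pf1.normal
        expected = rot.as_matrix() @ n0
        angle = math.degrees(math.acos(
            np.clip(abs(np.dot(expected, n1)), -1, 1)))
        assert angle < 0.2

    def test_collinear_rejected(self):
        t = np.arange(100) * 5e-4
        pos = np.outer(np.linspace(0, 1, 100), [1.0, 2.0, 3.0])
        with pytest.raises(GeometryError):
            geo.find_rotation_plane(Trajectory3D(times=t, positions=pos))

    def test_noiseless_error_decreases_with_points(self):
        errs = []
        for n in (100, 400, 1600):
            pf = geo.find_rotation_plane(
                circle_traj(theta=35.0, phi=120.0, n=n))
            errs.append(abs(pf.theta_deg - 35.0))
        assert all(e < 0.1 for e in errs)


class TestCircleFit:
    def test_exact_circle(self):
        traj = circle_traj(theta=35.0, phi=120.0, radius=250.0)
        pf = geo.find_rotation_plane(traj)
        cf = geo.project_and_fit_circle(traj, pf)
        assert cf.radius_nm == pytest.approx(250.0, rel=1e-9)
        assert cf.radial_rms_nm < 1e-6

    def test_noisy_radius_unbiased(self):
        """Isotropic σ = 10 nm noise: R unbiased within 1% at 2000 points."""
        radii = []
        for seed in range(5):
            traj = circle_traj(theta=20.0, phi=40.0, radius=250.0,
                               noise=10.0, seed=seed)
            pf = geo.find_rotation_plane(traj)
            cf = geo.project_and_fit_circle(traj, pf)
            radii.append(cf.radius_nm)
        assert np.mean(radii) == pytest.approx(250.0, rel=0.01)

    def test_partial_arc(self):
        """A semicircular arc still recovers R within 5%."""
        n = 800
        phases = np.linspace(0.0, np.pi, n)
        traj = circle_traj(theta=0.0, radius=250.0, n=n, phases=phases)
        # plane search needs spread; fit circle directly in the known plane
        pf = geo.PlaneFit(theta_deg=0.0, phi_deg=0.0,
                          center_nm=np.zeros(3), circularity_score=0.0,
                          out_of_plane_rms_nm=0.0)
        cf = geo.project_and_fit_circle(traj, pf)
        assert cf.radius_nm == pytest.approx(250.0, rel=0.05)


class TestEstimateRate:
    def test_uniform_rotation_rate(self):
        traj = circle_traj(theta=35.0, phi=120.0, rate=21.8)
        pf = geo.find_rotation_plane(traj)
        cf = geo.project_and_fit_circle(traj, pf)
        re = geo.estimate_rate(traj, pf, cf)
        assert re.rate_hz == pytest.approx(21.8, rel=1e-9)
        assert re.direction == "CCW"

    def test_time_reversal_antisymmetry(self):
        traj = circle_traj(theta=35.0, phi=120.0, rate=21.8)
        rev = Trajectory3D(times=traj.times, positions=traj.positions[::-1])
        pf = geo.find_rotation_plane(rev)
        cf = geo.project_and_fit_circle(rev, pf)
        re = geo.estimate_rate(rev, pf, cf)
        assert re.rate_hz == pytest.approx(21.8, rel=1e-9)
        assert re.direction == "CW"

    def test_insufficient_rotation(self):
        phases = np.linspace(0, 2.0, 500)  # 0.3 turns
        traj = circle_traj(n=500, phases=phases)
        pf = geo.find_rotation_plane(traj)
        cf = geo.project_and_fit_circle(traj, pf)
        with pytest.raises(GeometryError):
            geo.estimate_rate(traj, pf, cf)

    def test_langevin_rate_matches_model(self):
        """Simulated trace rate lies within 3 SE of T_a/2π(γ+γ_a)."""
        motor = syn.MotorParams(torque_pn_nm=160.0, gamma_a_pn_nm_s=0.81)
        marker = mk.MarkerGeometry.sphere(210.0, 250.0)
        sim = syn.SimParams(duration_s=2.0, seed=21)
        traj = syn.simulate_rotation_trace(motor, marker,
                                           syn.PlaneSpec(35.0, 120.0), sim)
        pf = geo.find_rotation_plane(traj)
        cf = geo.project_and_fit_circle(traj, pf)
        re = geo.estimate_rate(traj, pf, cf)
        expected = traj.meta["expected_rate_hz"]
        assert abs(re.rate_hz - expected) < 3 * re.rate_se_hz

    def test_rigid_motion_invariance(self):
        """Pipeline rate is invariant under rotation+translation (0.5%)."""
        from scipy.spatial.transform import Rotation
        traj = circle_traj(theta=35.0, phi=120.0, rate=21.8, noise=5.0)
        rot = Rotation.from_euler("xyz", [12.0, -30.0, 77.0], degrees=True)
        moved = Trajectory3D(
            times=traj.times,
            positions=traj.positions @ rot.as_matrix().T + [500, -300, 900])
        rates = []
        for tr in (traj, moved):
            pf = geo.find_rotation_plane(tr)
            cf = geo.project_and_fit_circle(tr, pf)
            rates.append(geo.estimate_rate(tr, pf, cf).rate_hz)
        assert abs(rates[1] - rates[0]) / rates[0] < 0.005


def modulated_phases(rate_hz, depth, n=4000, dt=5e-4, phase_offset=0.0):
    """Integrate dφ/dt = ω(1 − depth·cos(6(φ − offset)))."""
    w = 2 * math.pi * rate_hz
    ph = np.empty(n)
    ph[0] = 0.0
    for i in range(1, n):
        ph[i] = ph[i - 1] + w * (1 - depth * math.cos(
            6 * (ph[i - 1] - phase_offset))) * dt
    return ph


class TestQCTrace:
    def _report(self, phases):
        traj = circle_traj(theta=10.0, phi=30.0, n=len(phases),
                           phases=phases)
        pf = geo.find_rotation_plane(traj)
        cf = geo.project_and_fit_circle(traj, pf)
        return geo.qc_trace(traj, pf, cf)

    def test_constant_speed_accepted(self):
        qc = self._report(2 * np.pi * 10.0 * np.arange(4000) * 5e-4)
        assert qc.modulation_depth_60 < 0.01
        assert qc.accepted

    def test_sixty_degree_modulation_rejected(self):
        """Full-depth 60°-periodic speed modulation is the stepping
        signature and must be rejected."""
        qc = self._report(modulated_phases(5.0, 0.95))
        assert qc.modulation_depth_60 > 0.5
        assert not qc.accepted

    def test_phase_offset_invariance(self):
        a = self._report(modulated_phases(5.0, 0.95, phase_offset=0.0))
        b = self._report(modulated_phases(5.0, 0.95, phase_offset=0.4))
        assert a.accepted == b.accepted is False

    def test_dwelling_trace_rejected(self):
        """A long pause mid-trace violates the smoothness criterion."""
        t = np.arange(4000) * 5e-4
        w = 2 * math.pi * 10.0
        ph = np.where(t < 0.5, w * t,
                      np.where(t < 1.5, w * 0.5,
                               w * 0.5 + w * (t - 1.5)))
        qc = self._report(ph)
        assert not qc.smooth
        assert not qc.accepted

    def test_decision_deterministic(self):
        ph = modulated_phases(5.0, 0.6)
        assert self._report(ph).as_dict() == self._report(ph).as_dict()
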