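"""Generative models for the rotation assay.

Two generative motor models are implemented:

* **Model A** — the motor exerts a constant torque ``T_a`` against the
  total viscous drag (marker drag γ plus an internal drag-like constant
  ``γ_a``).  The angle follows the overdamped Langevin equation

      dθ/dt = T_a/(γ + γ_a) + sqrt(2 k_BT/(γ + γ_a)) ξ(t),

  integrated by Euler–Maruyama on a fine internal grid and decimated to
  camera frames.  The zero-temperature mean rate is exactly
  T_a / 2π(γ + γ_a).

* **Model B** — a rate-limiting chemical step triggers discrete steps of
  ``step_size`` degrees as a Poisson process at rate
  f_noload · (360/step_size); each step then relaxes viscously at
  angular speed T_a/γ (duration γ·δ/T_a for a step of δ rad).  The mean
  rate is (1/f_noload + 2πγ/T_a)⁻¹, which is algebraically the Model A
  curve with γ_a = T_a/2π·f_noload.

The benchmark-dataset builder emulates the published study conditions:
four marker size classes (210-nm, 490-nm and 1.0-µm beads and tethered
cells) with sample sizes 32/31/26/12, rates drawn from the constant-
torque model with multiplicative measurement noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import markers as mk
from .errors import ParameterError, StabilityError, ConfigError
from .hydrodynamics import marker_drag
from .optics import ImageStack, OpticsParams
from .trajectory import Trajectory3D
from .units import ETA_BUFFER, KBT_ROOM

MODEL_A = "model_A"
MODEL_B = "model_B"
CW = "CW"
CCW = "CCW"


@dataclass
class MotorParams:
    """Constant-torque motor with either viscous (A) or kinetic (B) limit.

    ``torque_pn_nm`` is T_a; ``gamma_a_pn_nm_s`` the internal drag-like
    constant (Model A); ``f_noload_hz`` the zero-load rate (Model B).
    """

    torque_pn_nm: float = 160.0
    gamma_a_pn_nm_s: float = 0.81
    mode: str = MODEL_A
    f_noload_hz: Optional[float] = None
    step_size_deg: float = 60.0
    direction: str = CCW

    def __post_init__(self) -> None:
        if self.torque_pn_nm <= 0:
            raise ParameterError("torque must be positive")
        if self.gamma_a_pn_nm_s < 0:
            raise ParameterError("gamma_a must be non-negative")
        if self.mode not in (MODEL_A, MODEL_B):
            raise ParameterError(f"unknown motor mode {self.mode!r}")
        if self.mode == MODEL_B:
            if self.f_noload_hz is None or self.f_noload_hz <= 0:
                raise ParameterError("model_B requires f_noload_hz > 0")
        if self.step_size_deg <= 0 or 360.0 % self.step_size_deg != 0:
            raise ParameterError("step_size_deg must divide 360")
        if self.direction not in (CW, CCW):
            raise ParameterError("direction must be 'CW' or 'CCW'")

    @property
    def sign(self) -> float:
        """CCW-positive angular sign convention."""
        return 1.0 if self.direction == CCW else -1.0


@dataclass
class SimParams:
    """Sampling and thermodynamic parameters of a simulated recording."""

    dt_s: float = 5e-4
    duration_s: float = 1.0
    k_bt_pn_nm: float = KBT_ROOM
    eta_pa_s: float = ETA_BUFFER
    seed: int = 0
    substeps: int = 10

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ParameterError("dt must be positive")
        if self.duration_s < 100 * self.dt_s:
            raise ParameterError("duration must cover at least 100 frames")
        if self.k_bt_pn_nm < 0:
            raise ParameterError("k_BT must be non-negative")
        if self.eta_pa_s <= 0:
            raise ParameterError("viscosity must be positive")
        if self.substeps < 1:
            raise ParameterError("substeps must be >= 1")


@dataclass
class PlaneSpec:
    """Orientation of the rotation plane: normal in polar coordinates."""

    theta_deg: float = 0.0
    phi_deg: float = 0.0
    center_nm: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_deg <= 90.0:
            raise ParameterError("theta must lie in [0, 90] degrees")
        if not 0.0 <= self.phi_deg < 360.0:
            raise ParameterError("phi must lie in [0, 360) degrees")


def plane_basis(theta_deg: float, phi_deg: float
                ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Right-handed orthonormal basis (u, v, n) for a plane with normal
    at polar angle θ, azimuth φ.  v = n × u, so phase advancing from u
    toward v is counter-clockwise about n."""
    th = math.radians(theta_deg)
    ph = math.radians(phi_deg)
    n = np.array([math.sin(th) * math.cos(ph),
                  math.sin(th) * math.sin(ph),
                  math.cos(th)])
    ref = np.array([0.0, 0.0, 1.0])
    if abs(n[2]) > 1.0 - 1e-12:
        u = np.array([1.0, 0.0, 0.0])
    else:
        u = np.cross(ref, n)
        u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v, n


# ---------------------------------------------------------------------------
# angle-level simulators
# ---------------------------------------------------------------------------

def simulate_angles(motor: MotorParams, gamma_load: float, sim: SimParams,
                    rng: Optional[np.random.Generator] = None
                    ) -> Tuple[np.ndarray, np.ndarray]:
    """Simulate the unwrapped motor angle θ(t) in radians.

    Returns ``(times, angles)`` sampled at the camera interval
    ``sim.dt_s`` (n_frames + 1 samples starting at t = 0, θ = 0).
    ``gamma_load`` is the drag of the attached marker in pN·nm·s.
    """
    if gamma_load < 0:
        raise ParameterError("marker drag must be non-negative")
    if rng is None:
        rng = np.random.default_rng(sim.seed)
    n_frames = int(round(sim.duration_s / sim.dt_s))
    times = np.arange(n_frames + 1) * sim.dt_s
    if motor.mode == MODEL_A:
        angles = _angles_model_a(motor, gamma_load, sim, n_frames, rng)
    else:
        angles = _angles_model_b(motor, gamma_load, times, rng)
    return times, motor.sign * angles


def _angles_model_a(motor: MotorParams, gamma_load: float, sim: SimParams,
                    n_frames: int, rng: np.random.Generator) -> np.ndarray:
    gamma_tot = gamma_load + motor.gamma_a_pn_nm_s
    if gamma_tot <= 0:
        raise ParameterError("total drag must be positive in model_A")
    dt_i = sim.dt_s / sim.substeps
    omega = motor.torque_pn_nm / gamma_tot  # rad/s
    if omega * dt_i > 0.5:
        raise StabilityError(
            f"internal step {dt_i:.2e}s advances {omega * dt_i:.2f} rad "
            "per step; reduce dt or increase substeps")
    n_sub = n_frames * sim.substeps
    increments = np.full(n_sub, omega * dt_i)
    if sim.k_bt_pn_nm > 0:
        diffusion = sim.k_bt_pn_nm / gamma_tot  # rad^2/s
        increments = increments + rng.normal(
            0.0, math.sqrt(2.0 * diffusion * dt_i), size=n_sub)
    theta = np.empty(n_sub + 1)
    theta[0] = 0.0
    np.cumsum(increments, out=theta[1:])
    return theta[::sim.substeps].copy()


def _angles_model_b(motor: MotorParams, gamma_load: float,
                    sample_times: np.ndarray, rng: np.random.Generator
                    ) -> np.ndarray:
    """Event-driven stepping: exponential dwells at rate f_noload·m
    followed by viscous slides of duration γ·δ/T_a, evaluated at the
    camera sample times by piecewise-linear interpolation."""
    delta = math.radians(motor.step_size_deg)
    steps_per_rev = 2.0 * math.pi / delta
    k = motor.f_noload_hz * steps_per_rev  # step trigger rate, 1/s
    slide = gamma_load * delta / motor.torque_pn_nm  # slide duration, s
    duration = float(sample_times[-1])
    mean_step_time = 1.0 / k + slide
    knots_t = [0.0]
    knots_th = [0.0]
    t = 0.0
    theta = 0.0
    # draw dwells in blocks until the recording is covered
    expected = int(duration / mean_step_time) + 10
    while t <= duration:
        dwells = rng.exponential(1.0 / k, size=max(expected, 64))
        for dw in dwells:
            t_start = t + dw
            t_end = t_start + slide
            theta_prev = theta
            theta += delta
            knots_t.extend((t_start, t_end))
            knots_th.extend((theta_prev, theta))
            t = t_end
            if t > duration:
                break
        expected = max(16, int((duration - t) / mean_step_time) + 10)
    kt = np.asarray(knots_t)
    kth = np.asarray(knots_th)
    # enforce strictly sorted knots (zero-duration slides at γ = 0)
    order = np.argsort(kt, kind="stable")
    return np.interp(sample_times, kt[order], kth[order])


def mean_rate_hz(motor: MotorParams, gamma_load: float) -> float:
    """Closed-form mean rotation rate of either generative model."""
    if motor.mode == MODEL_A:
        return motor.torque_pn_nm / (
            2.0 * math.pi * (gamma_load + motor.gamma_a_pn_nm_s))
    return 1.0 / (1.0 / motor.f_noload_hz
                  + 2.0 * math.pi * gamma_load / motor.torque_pn_nm)


# ---------------------------------------------------------------------------
# 3D trace simulation
# ---------------------------------------------------------------------------

def simulate_rotation_trace(motor: MotorParams, marker: mk.MarkerGeometry,
                            plane: PlaneSpec, sim: SimParams,
                            apply_wall_correction: bool = True
                            ) -> Trajectory3D:
    """Simulate the 3D orbit of a marker driven by the motor.

    The marker drag is computed from its geometry (wall-corrected for
    beads by default); the orbit radius is the bead rotation radius or,
    for a tethered cell, the cell length (far-pole lever arm).
    """
    est = marker_drag(marker, sim.eta_pa_s,
                      apply_wall_correction=apply_wall_correction)
    gamma = est.corrected
    rng = np.random.default_rng(sim.seed)
    times, angles = simulate_angles(motor, gamma, sim, rng)
    radius = marker.orbit_radius_nm
    u, v, _ = plane_basis(plane.theta_deg, plane.phi_deg)
    center = np.asarray(plane.center_nm, dtype=float)
    pos = (center[None, :]
           + radius * np.cos(angles)[:, None] * u[None, :]
           + radius * np.sin(angles)[:, None] * v[None, :])
    meta = {
        "model": motor.mode,
        "torque_pn_nm": motor.torque_pn_nm,
        "gamma_marker_pn_nm_s": gamma,
        "gamma_a_pn_nm_s": motor.gamma_a_pn_nm_s,
        "direction": motor.direction,
        "orbit_radius_nm": radius,
        "plane_theta_deg": plane.theta_deg,
        "plane_phi_deg": plane.phi_deg,
        "expected_rate_hz": mean_rate_hz(motor, gamma),
        "seed": sim.seed,
    }
    return Trajectory3D(times=times, positions=pos, meta=meta)


# ---------------------------------------------------------------------------
# dual-spot image rendering
# ---------------------------------------------------------------------------

def _pixel_profile(n: int, center: float, sigma: float) -> np.ndarray:
    """Pixel-integrated 1D Gaussian profile over n pixels."""
    from scipy.special import erf
    edges = np.arange(n + 1) - 0.5
    z = (edges - center) / (sigma * math.sqrt(2.0))
    cdf = 0.5 * (1.0 + erf(z))
    return np.diff(cdf)


def expected_dual_frame(position_nm: Sequence[float], optics: OpticsParams
                        ) -> np.ndarray:
    """Expected photon image (no noise) of one marker position."""
    rows, cols = optics.frame_shape
    cx, cy = optics.center_px
    ax, ay = optics.prism_axis
    ox, oy = optics.prism_offset_nm
    x_px = cx + (position_nm[0] + ox) / optics.pixel_size_nm
    y_px = cy + (position_nm[1] + oy) / optics.pixel_size_nm
    sep_px = ((optics.baseline_separation_nm
               + optics.axial_gain * position_nm[2]) / optics.pixel_size_nm)
    sigma = optics.psf_sigma_px
    img = np.zeros((rows, cols))
    for s in (-0.5, 0.5):
        sx = x_px + s * sep_px * ax
        sy = y_px + s * sep_px * ay
        px = _pixel_profile(cols, sx, sigma)
        py = _pixel_profile(rows, sy, sigma)
        img += optics.photons_per_spot * np.outer(py, px)
    return img


def render_dual_image_stack(traj: Trajectory3D, optics: OpticsParams,
                            seed: Optional[int] = None,
                            noise: bool = True) -> ImageStack:
    """Render prism-split dual-spot frames for a trajectory.

    Each frame holds two pixel-integrated Gaussian spots whose mean
    position encodes (x, y) and whose separation along the prism axis
    encodes z.  Poisson shot noise is applied per pixel (so the total
    photon count per spot is Poisson with the configured mean) plus
    Gaussian read noise on top of a constant camera offset.  With
    ``noise=False`` the expectation image is returned (camera offset
    still added) — useful for calibration fixtures.
    """
    rng = np.random.default_rng(seed)
    n = len(traj)
    rows, cols = optics.frame_shape
    frames = np.empty((n, rows, cols), dtype=np.uint16)
    warnings: List[str] = []
    min_sep_nm = 4.0 * optics.psf_sigma_nm
    for i in range(n):
        p = traj.positions[i]
        sep = optics.baseline_separation_nm + optics.axial_gain * p[2]
        if abs(sep) < min_sep_nm:
            warnings.append(
                f"frame {i}: spot separation {sep:.0f} nm below "
                f"separability threshold {min_sep_nm:.0f} nm")
        img = expected_dual_frame(p, optics)
        if noise:
            img = rng.poisson(img).astype(float)
            img += optics.camera_offset_counts
            if optics.read_noise_counts > 0:
                img += rng.normal(0.0, optics.read_noise_counts, img.shape)
        else:
            img = img + optics.camera_offset_counts
        frames[i] = np.clip(np.round(img), 0, 65535).astype(np.uint16)
    meta = {
        "pixel_nm": optics.pixel_size_nm,
        "dt_s": optics.frame_interval_s,
        "axial_gain": optics.axial_gain,
        "baseline": optics.baseline_separation_nm,
        "optics": optics.to_meta(),
        "warnings": warnings,
        "n_frames": n,
    }
    return ImageStack(frames=frames, meta=meta)


# ---------------------------------------------------------------------------
# benchmark dataset (Fig.-3-like study conditions)
# ---------------------------------------------------------------------------

DATASET_COLUMNS = ["marker_id", "kind", "diameter_nm", "rotation_radius_nm",
                   "cell_length_nm", "cell_radius_nm", "wall_gap_nm",
                   "rate_hz", "direction"]


@dataclass
class SizeClass:
    """One marker size class of the benchmark dataset."""

    kind: str
    n: int
    diameter_nm: Optional[float] = None
    wall_gap_nm: float = 500.0
    rotation_radius_mean_nm: float = 250.0
    rotation_radius_sd_nm: float = 50.0
    rotation_radius_range_nm: Tuple[float, float] = (120.0, 450.0)
    cell_length_range_nm: Tuple[float, float] = (2000.0, 4000.0)
    cell_radius_nm: float = 250.0


@dataclass
class BenchmarkConfig:
    """Study conditions of the benchmark: four size classes, constant-
    torque generator, 10% multiplicative rate noise."""

    classes: List[SizeClass] = field(default_factory=lambda: [
        SizeClass(kind=mk.SPHERE, n=32, diameter_nm=210.0),
        SizeClass(kind=mk.SPHERE, n=31, diameter_nm=490.0),
        SizeClass(kind=mk.SPHERE, n=26, diameter_nm=1000.0),
        SizeClass(kind=mk.ROD, n=12),
    ])
    motor: MotorParams = field(default_factory=MotorParams)
    eta_pa_s: float = ETA_BUFFER
    rate_cv: float = 0.10
    apply_wall_correction: bool = True

    def __post_init__(self) -> None:
        if not self.classes:
            raise ConfigError("benchmark config lists no size classes")
        if self.rate_cv < 0:
            raise ConfigError("rate_cv must be non-negative")


def build_benchmark_dataset(config: Optional[BenchmarkConfig] = None,
                            seed: int = 0) -> pd.DataFrame:
    """Generate a benchmark marker table (one row per marker).

    Geometry is randomized within each class (rotation radius for
    beads, cell length for tethered cells); the rotation rate is the
    closed-form constant-torque rate at the marker's wall-corrected
    drag, times multiplicative Gaussian measurement noise.  Bit-for-bit
    reproducible for a given seed.
    """
    if config is None:
        config = BenchmarkConfig()
    rng = np.random.default_rng(seed)
    rows = []
    idx = 0
    for cls_i, cls in enumerate(config.classes):
        if cls.n <= 0:
            raise ConfigError("size class with non-positive count")
        for _ in range(cls.n):
            if cls.kind == mk.SPHERE:
                radius = float(np.clip(
                    rng.normal(cls.rotation_radius_mean_nm,
                               cls.rotation_radius_sd_nm),
                    *cls.rotation_radius_range_nm))
                geom = mk.MarkerGeometry.sphere(
                    cls.diameter_nm, radius, wall_gap_nm=cls.wall_gap_nm)
            elif cls.kind == mk.ROD:
                length = float(rng.uniform(*cls.cell_length_range_nm))
                geom = mk.MarkerGeometry.tethered_cell(
                    length, cls.cell_radius_nm)
            else:
                raise ConfigError(f"unsupported benchmark kind {cls.kind!r}")
            gamma = marker_drag(
                geom, config.eta_pa_s,
                apply_wall_correction=config.apply_wall_correction).corrected
            rate = mean_rate_hz(config.motor, gamma)
            if config.rate_cv > 0:
                rate *= max(1e-6, 1.0 + config.rate_cv * rng.normal())
            direction = CCW if rng.random() < 0.5 else CW
            rows.append({
                "marker_id": f"m{idx:03d}",
                "kind": geom.kind,
                "diameter_nm": geom.diameter_nm,
                "rotation_radius_nm": geom.rotation_radius_nm,
                "cell_length_nm": geom.cell_length_nm,
                "cell_radius_nm": geom.cell_radius_nm,
                "wall_gap_nm": geom.wall_gap_nm if geom.kind == mk.SPHERE else None,
                "rate_hz": rate,
                "direction": direction,
            })
            idx += 1
    return pd.DataFrame(rows, columns=DATASET_COLUMNS)
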