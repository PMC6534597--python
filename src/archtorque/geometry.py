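"""Rotation-plane search, circle fitting, rate estimation and trace QC.

The orbit of a marker attached to an obliquely protruding filament is an
ellipse in the camera (x, y) plane but a circle in its true rotation
plane.  That plane is found by a rotational search of the two polar
angles (θ, φ) of the plane normal, minimizing the coefficient of
variation of the in-plane radial distances (perfect circle → CV = 0).
An SVD plane fit seeds the search; a local grid at 1° refined to 0.1°
and a final simplex polish recover the angles.

Rates are estimated from the slope of the unwrapped in-plane phase
versus time, which uses every frame and yields a standard error.  The
sign convention is CCW-positive about the plane normal oriented toward
+z (the camera viewpoint of an inverted microscope).

QC mirrors the published selection: traces whose speed is strongly
modulated with a 60° period (the signature of the stepping regime) or
that dwell are excluded from torque estimation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import least_squares, minimize
from scipy.stats import linregress

from .errors import GeometryError
from .synthetic import CCW, CW, plane_basis
from .trajectory import Trajectory3D


@dataclass
class PlaneFit:
    """Best-fit rotation plane: normal direction in polar coordinates."""

    theta_deg: float
    phi_deg: float
    center_nm: np.ndarray  # 3-vector
    circularity_score: float  # CV of in-plane radii (0 = perfect circle)
    out_of_plane_rms_nm: float

    def basis(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        return plane_basis(self.theta_deg, self.phi_deg)

    @property
    def normal(self) -> np.ndarray:
        return self.basis()[2]

    def as_dict(self) -> dict:
        return {"theta_deg": self.theta_deg, "phi_deg": self.phi_deg,
                "center_nm": list(np.asarray(self.center_nm)),
                "circularity_score": self.circularity_score,
                "out_of_plane_rms_nm": self.out_of_plane_rms_nm}


@dataclass
class CircleFit:
    """Circle fitted to the in-plane projection."""

    radius_nm: float
    center_inplane_nm: Tuple[float, float]
    radial_rms_nm: float
    low_signal: bool = False

    def as_dict(self) -> dict:
        return {"radius_nm": self.radius_nm,
                "center_inplane_nm": list(self.center_inplane_nm),
                "radial_rms_nm": self.radial_rms_nm,
                "low_signal": self.low_signal}


@dataclass
class RateEstimate:
    """Signed rotation rate from the phase-vs-time regression."""

    rate_hz: float
    direction: str
    rate_se_hz: float
    phase_rad: np.ndarray = field(repr=False)
    times_s: np.ndarray = field(repr=False)

    def as_dict(self) -> dict:
        return {"rate_hz": self.rate_hz, "direction": self.direction,
                "rate_se_hz": self.rate_se_hz,
                "n_turns": float(abs(self.phase_rad[-1] - self.phase_rad[0])
                                 / (2 * math.pi))}


@dataclass
class QCReport:
    """Smooth-rotation selection verdict for one trace."""

    modulation_depth_60: float
    smooth: bool
    accepted: bool
    reason: str = ""

    def as_dict(self) -> dict:
        return {"modulation_depth_60": self.modulation_depth_60,
                "smooth": self.smooth, "accepted": self.accepted,
                "reason": self.reason}


# ---------------------------------------------------------------------------
# plane search
# ---------------------------------------------------------------------------

def _normal_to_angles(n: np.ndarray) -> Tuple[float, float]:
    if n[2] < 0:
        n = -n
    theta = math.degrees(math.acos(np.clip(n[2], -1.0, 1.0)))
    phi = math.degrees(math.atan2(n[1], n[0])) % 360.0
    return theta, phi


def _radial_cv(points: np.ndarray, theta_deg: float, phi_deg: float) -> float:
    """CV of radii of the in-plane projection around the Kåsa centre."""
    u, v, _ = plane_basis(theta_deg, phi_deg)
    xy = points @ np.column_stack([u, v])
    cx, cy, _ = _kasa(xy)
    r = np.hypot(xy[:, 0] - cx, xy[:, 1] - cy)
    mean = r.mean()
    if mean <= 0:
        return np.inf
    return float(r.std() / mean)


def _kasa(xy: np.ndarray) -> Tuple[float, float, float]:
    """Algebraic (Kåsa) circle fit: returns (cx, cy, R)."""
    x, y = xy[:, 0], xy[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    R = math.sqrt(max(c + cx**2 + cy**2, 0.0))
    return float(cx), float(cy), R


def find_rotation_plane(traj: Trajectory3D, min_points: int = 50) -> PlaneFit:
    """Rotational search for the plane in which the orbit is circular.

    Raises :class:`GeometryError` on degenerate (collinear or too-short)
    input.  Resolution: 1° coarse grid around the SVD seed, 0.1°
    refinement, then a continuous simplex polish.
    """
    pts = traj.good_positions()
    if len(pts) < min_points:
        raise GeometryError(f"need >= {min_points} usable points")
    centroid = pts.mean(axis=0)
    X = pts - centroid
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    if s[0] <= 0 or s[1] / s[0] < 1e-8:
        raise GeometryError("degenerate trajectory: points are collinear")
    theta0, phi0 = _normal_to_angles(vt[2])

    def obj(angles) -> float:
        th = float(np.clip(angles[0], 0.0, 90.0))
        return _radial_cv(X, th, angles[1] % 360.0)

    best = (obj((theta0, phi0)), theta0, phi0)
    for span, step in ((10.0, 1.0), (1.0, 0.1)):
        _, th_c, ph_c = best
        th_grid = np.arange(th_c - span, th_c + span + step / 2, step)
        ph_grid = np.arange(ph_c - span, ph_c + span + step / 2, step)
        for th in th_grid:
            if not 0.0 <= th <= 90.0:
                continue
            for ph in ph_grid:
                val = obj((th, ph))
                if val < best[0]:
                    best = (val, float(th), float(ph % 360.0))
    res = minimize(obj, x0=[best[1], best[2]], method="Nelder-Mead",
                   options={"xatol": 1e-3, "fatol": 1e-12, "maxiter": 400})
    if res.fun < best[0]:
        best = (float(res.fun), float(np.clip(res.x[0], 0, 90)),
                float(res.x[1] % 360.0))
    cv, theta, phi = best
    u, v, n = plane_basis(theta, phi)
    xy = X @ np.column_stack([u, v])
    cx, cy, _ = _kasa(xy)
    center = centroid + cx * u + cy * v
    oop = float(np.std(X @ n))
    return PlaneFit(theta_deg=theta, phi_deg=phi, center_nm=center,
                    circularity_score=cv, out_of_plane_rms_nm=oop)


# ---------------------------------------------------------------------------
# circle fit
# ---------------------------------------------------------------------------

def project_to_plane(traj: Trajectory3D, plane: PlaneFit) -> np.ndarray:
    """In-plane 2D coordinates (nm) of the good frames, relative to the
    plane centre."""
    u, v, _ = plane.basis()
    X = traj.good_positions() - np.asarray(plane.center_nm)
    return X @ np.column_stack([u, v])


def project_and_fit_circle(traj: Trajectory3D, plane: PlaneFit,
                           noise_floor_nm: float = 0.0) -> CircleFit:
    """Kåsa circle fit refined by geometric least squares."""
    xy = project_to_plane(traj, plane)
    cx, cy, R = _kasa(xy)

    def resid(p):
        return np.hypot(xy[:, 0] - p[0], xy[:, 1] - p[1]) - p[2]

    sol = least_squares(resid, x0=[cx, cy, R])
    cx, cy, R = sol.x
    if R <= 0:
        raise GeometryError("degenerate circle fit (non-positive radius)")
    rms = float(np.sqrt(np.mean(resid(sol.x) ** 2)))
    low = noise_floor_nm > 0 and R < 3.0 * noise_floor_nm
    return CircleFit(radius_nm=float(R), center_inplane_nm=(float(cx), float(cy)),
                     radial_rms_nm=rms, low_signal=bool(low))


# ---------------------------------------------------------------------------
# rate estimation
# ---------------------------------------------------------------------------

def unwrapped_phase(traj: Trajectory3D, plane: PlaneFit,
                    circle: CircleFit) -> Tuple[np.ndarray, np.ndarray]:
    """Unwrapped in-plane phase (rad) and times of the good frames."""
    xy = project_to_plane(traj, plane)
    cx, cy = circle.center_inplane_nm
    phase = np.unwrap(np.arctan2(xy[:, 1] - cy, xy[:, 0] - cx))
    return traj.times[traj.good], phase


def estimate_rate(traj: Trajectory3D, plane: PlaneFit,
                  circle: CircleFit) -> RateEstimate:
    """Rotation rate from the least-squares line of phase vs time.

    Requires at least one full turn of net rotation.  CCW-positive
    about the plane normal (oriented toward +z, θ ≤ 90°).
    """
    t, phase = unwrapped_phase(traj, plane, circle)
    net = abs(phase[-1] - phase[0])
    if net < 2.0 * math.pi:
        raise GeometryError(
            f"net rotation {net / (2 * math.pi):.2f} turns < 1; "
            "rate not estimable")
    res = linregress(t, phase)
    rate = abs(res.slope) / (2.0 * math.pi)
    direction = CCW if res.slope > 0 else CW
    # Phase residuals are strongly autocorrelated for diffusive traces,
    # so the i.i.d. regression stderr is optimistic; a batch-means SE
    # over >= 8 blocks is robust to both diffusion and tracking noise.
    se = float(res.stderr)
    n_blocks = 8
    if len(t) >= 16 * n_blocks:
        edges = np.linspace(0, len(t), n_blocks + 1).astype(int)
        slopes = [linregress(t[a:b], phase[a:b]).slope
                  for a, b in zip(edges[:-1], edges[1:])]
        se = max(se, float(np.std(slopes, ddof=1) / math.sqrt(n_blocks)))
    return RateEstimate(rate_hz=float(rate), direction=direction,
                        rate_se_hz=se / (2.0 * math.pi),
                        phase_rad=phase, times_s=t)


# ---------------------------------------------------------------------------
# trace QC (smooth-rotation selection)
# ---------------------------------------------------------------------------

def qc_trace(traj: Trajectory3D, plane: PlaneFit, circle: CircleFit,
             period_deg: float = 60.0, depth_threshold: float = 0.5,
             dwell_factor: float = 5.0) -> QCReport:
    """Detect the stepping signature (periodic speed changes, dwells).

    Instantaneous speed is binned by phase modulo ``period_deg`` (12
    bins for 60°); the modulation depth is (max − min)/mean of the bin
    medians.  A trace is *smooth* when no interval between successive
    ``period_deg`` boundary crossings exceeds ``dwell_factor`` times
    the median interval.  accepted = smooth ∧ depth < threshold.
    """
    t, phase = unwrapped_phase(traj, plane, circle)
    if len(t) < 10:
        return QCReport(modulation_depth_60=math.inf, smooth=False,
                        accepted=False, reason="too few frames")
    dt = np.diff(t)
    speed = np.diff(phase) / dt  # rad/s at interval midpoints
    mid_phase = 0.5 * (phase[:-1] + phase[1:])
    period = math.radians(period_deg)
    frac = np.mod(mid_phase, period) / period
    n_bins = 12
    bins = np.minimum((frac * n_bins).astype(int), n_bins - 1)
    medians = np.array([np.median(np.abs(speed[bins == b]))
                        for b in range(n_bins) if np.any(bins == b)])
    if len(medians) < n_bins // 2 or medians.mean() == 0:
        return QCReport(modulation_depth_60=math.inf, smooth=False,
                        accepted=False, reason="phase coverage too sparse")
    depth = float((medians.max() - medians.min()) / medians.mean())

    # dwell check: first-passage times of successive period boundaries
    sgn = 1.0 if phase[-1] >= phase[0] else -1.0
    ph = np.maximum.accumulate(sgn * phase)  # monotone envelope vs noise
    levels = np.arange(math.ceil(ph[0] / period) + 1,
                       math.floor(ph[-1] / period) + 1) * period
    idx = np.minimum(np.searchsorted(ph, levels), len(t) - 1)
    crossings = t[idx]
    smooth = True
    reason = ""
    if len(crossings) >= 4:
        intervals = np.diff(crossings)
        med = np.median(intervals)
        if med > 0 and intervals.max() > dwell_factor * med:
            smooth = False
            reason = (f"dwell {intervals.max():.3g}s exceeds "
                      f"{dwell_factor}x median interval {med:.3g}s")
    accepted = smooth and depth < depth_threshold
    if accepted:
        reason = "smooth rotation"
    elif smooth and depth >= depth_threshold:
        reason = (f"{period_deg:.0f}-degree speed modulation depth "
                  f"{depth:.2f} >= {depth_threshold}")
    return QCReport(modulation_depth_60=depth, smooth=smooth,
                    accepted=accepted, reason=reason)


def analyze_trajectory(traj: Trajectory3D, noise_floor_nm: float = 0.0,
                       qc_kwargs: Optional[dict] = None) -> dict:
    """Full per-trajectory analysis record: plane, circle, rate, QC."""
    plane = find_rotation_plane(traj)
    circle = project_and_fit_circle(traj, plane, noise_floor_nm=noise_floor_nm)
    rate = estimate_rate(traj, plane, circle)
    qc = qc_trace(traj, plane, circle, **(qc_kwargs or {}))
    return {"plane": plane.as_dict(), "circle": circle.as_dict(),
            "rate": rate.as_dict(), "qc": qc.as_dict()}
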