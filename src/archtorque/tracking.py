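"""Recover 3D trajectories from prism-split dual-spot image stacks.

Per frame, both spots are localized by sub-pixel 2D Gaussian fitting,
paired along the prism axis, and reduced to a 3D position: the pair
mean gives (x, y), the pair separation gives z through a linear axial
calibration (separation = intercept + slope · z).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress
from skimage.feature import peak_local_max

from .errors import CalibrationError, TrackingError
from .optics import ImageStack, OpticsParams
from .trajectory import (FLAG_NO_SPOT, FLAG_OK, FLAG_PAIRING, Trajectory3D)

FIT_WINDOW = 7  # px, Gaussian fit window (odd)


@dataclass
class SpotFit:
    """One localized spot: sub-pixel centre, intensity, fit residual."""

    x_px: float
    y_px: float
    intensity: float  # integrated photons above background
    sigma_px: float
    background: float
    residual_rms: float
    merged: bool = False


@dataclass
class AxialCalibration:
    """Linear map between spot-pair separation and axial position."""

    slope: float  # nm separation per nm z
    intercept_nm: float
    residual_rms_nm: float
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise CalibrationError("axial calibration slope must be non-zero")
        if self.residual_rms_nm < 0:
            raise CalibrationError("residual RMS must be non-negative")

    def z_from_separation(self, separation_nm: float) -> float:
        return (separation_nm - self.intercept_nm) / self.slope

    def as_dict(self) -> dict:
        return {"slope": self.slope, "intercept_nm": self.intercept_nm,
                "residual_rms_nm": self.residual_rms_nm,
                "n_points": self.n_points}

    @classmethod
    def from_optics(cls, optics: OpticsParams) -> "AxialCalibration":
        """Nominal calibration taken from the rendering optics."""
        return cls(slope=optics.axial_gain,
                   intercept_nm=optics.baseline_separation_nm,
                   residual_rms_nm=0.0)


def _gauss_model(grid: Tuple[np.ndarray, np.ndarray], amp: float, x0: float,
                 y0: float, sigma: float, bg: float) -> np.ndarray:
    """Pixel-integrated 2D Gaussian on a pixel grid (flattened)."""
    from scipy.special import erf
    xs, ys = grid
    sq = sigma * math.sqrt(2.0)
    fx = 0.5 * (erf((xs + 0.5 - x0) / sq) - erf((xs - 0.5 - x0) / sq))
    fy = 0.5 * (erf((ys + 0.5 - y0) / sq) - erf((ys - 0.5 - y0) / sq))
    return (amp * fx * fy + bg).ravel()


def localize_spots(frame: np.ndarray, optics: OpticsParams,
                   max_spots: int = 2,
                   threshold_rel: float = 0.3) -> List[SpotFit]:
    """Sub-pixel spot centres from 2D Gaussian least squares.

    Candidate maxima above ``threshold_rel`` of the frame's peak
    (background-subtracted) seed a pixel-integrated Gaussian fit in a
    7×7 window; the window-edge median estimates the local background.
    Returns an empty list when nothing rises above threshold.
    """
    img = np.asarray(frame, dtype=float)
    bg_global = float(np.median(img))
    span = img.max() - bg_global
    if span <= 0:
        return []
    peaks = peak_local_max(img - bg_global, min_distance=3,
                           threshold_abs=threshold_rel * span,
                           num_peaks=max_spots, exclude_border=False)
    half = FIT_WINDOW // 2
    fits: List[SpotFit] = []
    for r, c in peaks:
        r0, r1 = r - half, r + half + 1
        c0, c1 = c - half, c + half + 1
        if r0 < 0 or c0 < 0 or r1 > img.shape[0] or c1 > img.shape[1]:
            continue  # too close to the frame edge for a full window
        win = img[r0:r1, c0:c1]
        edge = np.concatenate([win[0], win[-1], win[1:-1, 0], win[1:-1, -1]])
        bg = float(np.median(edge))
        ys, xs = np.mgrid[r0:r1, c0:c1]
        grid = (xs.astype(float).ravel(), ys.astype(float).ravel())
        p0 = (max(win.sum() - bg * win.size, 1.0), float(c), float(r),
              optics.psf_sigma_px, bg)
        try:
            popt, _ = curve_fit(
                _gauss_model, grid, win.ravel(), p0=p0,
                bounds=([0, c0 - 1, r0 - 1, 0.3, -np.inf],
                        [np.inf, c1, r1, FIT_WINDOW, np.inf]),
                maxfev=400)
        except RuntimeError:
            continue
        resid = win.ravel() - _gauss_model(grid, *popt)
        fits.append(SpotFit(x_px=float(popt[1]), y_px=float(popt[2]),
                            intensity=float(popt[0]),
                            sigma_px=float(popt[3]),
                            background=float(popt[4]),
                            residual_rms=float(np.sqrt(np.mean(resid**2)))))
    # flag overlapping fits (windows closer than the window size)
    for i, a in enumerate(fits):
        for b in fits[i + 1:]:
            if math.hypot(a.x_px - b.x_px, a.y_px - b.y_px) < FIT_WINDOW:
                a.merged = b.merged = True
    return fits


def _pair_separation(fits: Sequence[SpotFit], optics: OpticsParams
                     ) -> Optional[Tuple[float, float, float]]:
    """Pair the two spots along the prism axis.

    Returns (mean_x_px, mean_y_px, separation_nm) or None if no valid
    pair exists.  A valid pair lies within ±30% of the baseline
    separation when projected on the prism axis.
    """
    if len(fits) < 2:
        return None
    ax, ay = optics.prism_axis
    base_px = optics.baseline_separation_nm / optics.pixel_size_nm
    best = None
    for i in range(len(fits)):
        for j in range(i + 1, len(fits)):
            a, b = fits[i], fits[j]
            proj = abs((b.x_px - a.x_px) * ax + (b.y_px - a.y_px) * ay)
            if not 0.7 * base_px <= proj <= 1.3 * base_px:
                continue
            score = abs(proj - base_px)
            if best is None or score < best[0]:
                best = (score, a, b, proj)
    if best is None:
        return None
    _, a, b, proj = best
    return ((a.x_px + b.x_px) / 2.0, (a.y_px + b.y_px) / 2.0,
            proj * optics.pixel_size_nm)


def frame_separation(frame: np.ndarray, optics: OpticsParams
                     ) -> Optional[float]:
    """Spot-pair separation (nm) of a single frame, or None."""
    pair = _pair_separation(localize_spots(frame, optics), optics)
    return None if pair is None else pair[2]


def calibrate_axial(stack: ImageStack, z_positions_nm: Sequence[float],
                    optics: Optional[OpticsParams] = None
                    ) -> AxialCalibration:
    """Least-squares line of spot-pair separation vs known z.

    Requires at least three distinct z values (a two-point line would
    hide any nonlinearity and gives no residual estimate).
    """
    if optics is None:
        optics = stack.optics()
    z = np.asarray(z_positions_nm, dtype=float)
    if len(z) != len(stack):
        raise CalibrationError("one z position per frame required")
    if len(np.unique(z)) < 3:
        raise CalibrationError("need >= 3 distinct z positions")
    seps, zs = [], []
    for i in range(len(stack)):
        s = frame_separation(stack.frames[i], optics)
        if s is not None:
            seps.append(s)
            zs.append(z[i])
    if len(np.unique(zs)) < 3:
        raise CalibrationError("fewer than 3 frames yielded a spot pair")
    res = linregress(zs, seps)
    pred = res.intercept + res.slope * np.asarray(zs)
    rms = float(np.sqrt(np.mean((np.asarray(seps) - pred) ** 2)))
    return AxialCalibration(slope=float(res.slope),
                            intercept_nm=float(res.intercept),
                            residual_rms_nm=rms, n_points=len(zs))


def reconstruct_3d(stack: ImageStack, calibration: AxialCalibration,
                   optics: Optional[OpticsParams] = None,
                   max_failure_fraction: float = 0.2) -> Trajectory3D:
    """Reduce a dual-spot stack to a 3D trajectory.

    Lateral position is the pair mean (prism offset removed); z comes
    from the calibrated separation.  Frames without a valid pair are
    flagged (NaN position), never dropped; if more than
    ``max_failure_fraction`` of frames fail, the stack is rejected.
    """
    if optics is None:
        optics = stack.optics()
    n = len(stack)
    dt = stack.meta.get("dt_s", optics.frame_interval_s)
    cx, cy = optics.center_px
    ox, oy = optics.prism_offset_nm
    pos = np.full((n, 3), np.nan)
    flags = np.zeros(n, dtype=int)
    for i in range(n):
        fits = localize_spots(stack.frames[i], optics)
        if not fits:
            flags[i] = FLAG_NO_SPOT
            continue
        pair = _pair_separation(fits, optics)
        if pair is None:
            flags[i] = FLAG_PAIRING
            continue
        mx, my, sep = pair
        pos[i, 0] = (mx - cx) * optics.pixel_size_nm - ox
        pos[i, 1] = (my - cy) * optics.pixel_size_nm - oy
        pos[i, 2] = calibration.z_from_separation(sep)
    n_bad = int(np.count_nonzero(flags))
    if n and n_bad / n > max_failure_fraction:
        raise TrackingError(
            f"pairing failed on {n_bad}/{n} frames "
            f"(> {max_failure_fraction:.0%}); stack rejected")
    times = np.arange(n) * dt
    return Trajectory3D(times=times, positions=pos, flags=flags,
                        meta={"calibration": calibration.as_dict(),
                              "n_failed_frames": n_bad})
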