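"""Constant-torque model fitting across marker loads.

The central model: a motor that outputs constant torque T_a against the
viscous drag of the attached marker (γ) plus a load-independent
drag-like constant γ_a rotates at

    f(γ) = T_a / 2π(γ + γ_a).

γ_a is interpretable either as the drag of the filament itself
(Model A) or, through γ_a = T_a/2π·f_noload, as the signature of a
rate-limiting chemical step with zero-load rate f_noload (Model B);
the fitted curve is identical either way.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import linregress

from . import markers as mk
from .errors import IdentifiabilityError, ParameterError
from .hydrodynamics import marker_drag
from .units import ETA_BUFFER


@dataclass
class MarkerRecord:
    """One analyzed marker: geometry, measured rate, derived drags."""

    marker_id: str
    geometry: mk.MarkerGeometry
    rate_hz: float
    rate_se_hz: Optional[float] = None
    gamma_raw: Optional[float] = None
    gamma_corrected: Optional[float] = None
    qc_accepted: bool = True

    def __post_init__(self) -> None:
        if self.qc_accepted and not self.rate_hz > 0:
            raise ParameterError("accepted records need rate_hz > 0")


def marker_friction(record: MarkerRecord, eta_pa_s: float = ETA_BUFFER,
                    apply_wall_correction: bool = True) -> MarkerRecord:
    """Fill the γ fields of a record from its geometry.

    Spheres receive the near-wall correction factor on the full
    two-term drag (when enabled); tethered cells never do.
    """
    est = marker_drag(record.geometry, eta_pa_s,
                      apply_wall_correction=apply_wall_correction)
    record.gamma_raw = est.gamma
    record.gamma_corrected = est.corrected
    return record


def records_from_dataset(df: pd.DataFrame, eta_pa_s: float = ETA_BUFFER,
                         apply_wall_correction: bool = True
                         ) -> List[MarkerRecord]:
    """Build records from a benchmark dataset table (CSV dialect)."""
    records = []
    for _, row in df.iterrows():
        if row["kind"] == mk.SPHERE:
            geom = mk.MarkerGeometry.sphere(
                row["diameter_nm"], row["rotation_radius_nm"],
                wall_gap_nm=row["wall_gap_nm"] if pd.notna(row["wall_gap_nm"])
                else 500.0)
        elif row["kind"] == mk.ROD:
            geom = mk.MarkerGeometry.tethered_cell(
                row["cell_length_nm"], row["cell_radius_nm"])
        else:
            raise ParameterError(f"unsupported marker kind {row['kind']!r}")
        rec = MarkerRecord(marker_id=str(row["marker_id"]), geometry=geom,
                           rate_hz=float(row["rate_hz"]),
                           qc_accepted=bool(row.get("qc_accepted", True)))
        records.append(marker_friction(rec, eta_pa_s,
                                       apply_wall_correction))
    return records


@dataclass
class TorqueFit:
    """Fitted constant-torque model with bootstrap uncertainties."""

    torque_pn_nm: float
    gamma_a_pn_nm_s: float
    variant: str
    n_markers: int
    covariance: np.ndarray = field(repr=False)
    ci_torque: Tuple[float, float] = (math.nan, math.nan)
    ci_gamma_a: Tuple[float, float] = (math.nan, math.nan)
    n_bootstrap: int = 0
    seed: Optional[int] = None

    @property
    def f_noload_hz(self) -> float:
        """Zero-load rate implied by the kinetic reading of γ_a."""
        return model_b_f_noload(self.torque_pn_nm, self.gamma_a_pn_nm_s)

    def predict(self, gamma: np.ndarray) -> np.ndarray:
        return rate_model(np.asarray(gamma, dtype=float),
                          self.torque_pn_nm, self.gamma_a_pn_nm_s)

    def as_dict(self) -> dict:
        return {
            "torque_pn_nm": self.torque_pn_nm,
            "gamma_a_pn_nm_s": self.gamma_a_pn_nm_s,
            "f_noload_hz": self.f_noload_hz,
            "variant": self.variant,
            "n_markers": self.n_markers,
            "ci95_torque_pn_nm": list(self.ci_torque),
            "ci95_gamma_a_pn_nm_s": list(self.ci_gamma_a),
            "n_bootstrap": self.n_bootstrap,
            "seed": self.seed,
        }


def rate_model(gamma: np.ndarray, torque: float, gamma_a: float) -> np.ndarray:
    """f(γ) = T_a / 2π(γ + γ_a)."""
    return torque / (2.0 * math.pi * (gamma + gamma_a))


def _gammas_rates(records: Union[Sequence[MarkerRecord], pd.DataFrame],
                  variant: str
                  ) -> Tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]:
    if variant not in ("raw", "corrected"):
        raise ParameterError("variant must be 'raw' or 'corrected'")
    if isinstance(records, pd.DataFrame):
        df = records
        if "qc_accepted" in df.columns:
            df = df[df["qc_accepted"]]
        g = df["gamma_raw" if variant == "raw" else "gamma_corrected"]
        se = df["rate_se_hz"].to_numpy() if "rate_se_hz" in df.columns else None
        return g.to_numpy(float), df["rate_hz"].to_numpy(float), se
    recs = [r for r in records if r.qc_accepted]
    g = np.array([r.gamma_raw if variant == "raw" else r.gamma_corrected
                  for r in recs], dtype=float)
    f = np.array([r.rate_hz for r in recs], dtype=float)
    ses = [r.rate_se_hz for r in recs]
    se = (np.array(ses, dtype=float)
          if all(s is not None and s > 0 for s in ses) else None)
    return g, f, se


def _fit_core(g: np.ndarray, f: np.ndarray,
              se: Optional[np.ndarray]) -> Tuple[float, float, np.ndarray]:
    # initialization from the linearization 1/f = (2π/T)γ + 2πγ_a/T
    lin = linregress(g, 1.0 / f)
    if lin.slope > 0:
        t0 = 2.0 * math.pi / lin.slope
        ga0 = max(lin.intercept / lin.slope, 0.0)
    else:  # pathological (e.g. noiseless flat data): fall back
        t0 = float(2.0 * math.pi * np.median(g * f))
        ga0 = 0.0
    popt, pcov = curve_fit(rate_model, g, f, p0=[t0, ga0],
                           sigma=se, absolute_sigma=False,
                           bounds=([0.0, 0.0], [np.inf, np.inf]),
                           maxfev=2000)
    return float(popt[0]), float(popt[1]), pcov


def fit_constant_torque(records: Union[Sequence[MarkerRecord], pd.DataFrame],
                        variant: str = "corrected",
                        n_bootstrap: int = 1000,
                        seed: int = 0) -> TorqueFit:
    """Nonlinear least squares of f = T_a/2π(γ + γ_a).

    Per-point weights 1/SE²(f) are used when every record carries a
    rate SE, else the fit is unweighted and performed in f-space (the
    reciprocal linearization serves only as the initial guess).  95%
    confidence intervals come from case-resampling bootstrap
    (percentile method, seeded).
    """
    g, f, se = _gammas_rates(records, variant)
    if len(g) < 3:
        raise IdentifiabilityError("need >= 3 accepted records")
    if np.ptp(g) == 0:
        raise IdentifiabilityError("all γ identical: T_a and γ_a are "
                                   "not separately identifiable")
    if g.max() / g.min() < 10.0:
        _warnings.warn("γ span below one decade; γ_a poorly constrained",
                       stacklevel=2)
    torque, gamma_a, pcov = _fit_core(g, f, se)
    ci_t = (math.nan, math.nan)
    ci_ga = (math.nan, math.nan)
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        boot = np.empty((n_bootstrap, 2))
        n = len(g)
        kept = 0
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            if np.ptp(g[idx]) == 0:
                continue
            try:
                bt, bga, _ = _fit_core(g[idx], f[idx],
                                       None if se is None else se[idx])
            except RuntimeError:
                continue
            boot[kept] = (bt, bga)
            kept += 1
        if kept >= max(10, n_bootstrap // 2):
            q = np.percentile(boot[:kept], [2.5, 97.5], axis=0)
            ci_t = (float(q[0, 0]), float(q[1, 0]))
            ci_ga = (float(q[0, 1]), float(q[1, 1]))
    return TorqueFit(torque_pn_nm=torque, gamma_a_pn_nm_s=gamma_a,
                     variant=variant, n_markers=len(g), covariance=pcov,
                     ci_torque=ci_t, ci_gamma_a=ci_ga,
                     n_bootstrap=n_bootstrap, seed=seed)


def apparent_torque_curve(records: Union[Sequence[MarkerRecord], pd.DataFrame],
                          fit: TorqueFit) -> pd.DataFrame:
    """Apparent torque per marker, with and without the γ_a term.

    ``torque_load`` = 2πγf accounts only for the marker drag and
    declines with f when γ_a > 0; ``torque_total`` = 2π(γ + γ_a)f
    scatters around T_a with no trend under the constant-torque model.
    """
    g, f, _ = _gammas_rates(records, fit.variant)
    return pd.DataFrame({
        "rate_hz": f,
        "gamma_pn_nm_s": g,
        "torque_load_pn_nm": 2.0 * math.pi * g * f,
        "torque_total_pn_nm": 2.0 * math.pi * (g + fit.gamma_a_pn_nm_s) * f,
    })


def model_b_gamma_a(torque_pn_nm: float, f_noload_hz: float) -> float:
    """Kinetic reading: γ_a = T_a / 2π·f_noload."""
    if torque_pn_nm <= 0 or f_noload_hz <= 0:
        raise ParameterError("torque and f_noload must be positive")
    return torque_pn_nm / (2.0 * math.pi * f_noload_hz)


def model_b_f_noload(torque_pn_nm: float, gamma_a_pn_nm_s: float) -> float:
    """Inverse conversion: f_noload = T_a / 2π·γ_a."""
    if torque_pn_nm <= 0 or gamma_a_pn_nm_s <= 0:
        raise ParameterError("torque and gamma_a must be positive")
    return torque_pn_nm / (2.0 * math.pi * gamma_a_pn_nm_s)


def fit_rate_vs_diameter(diameters_nm: Sequence[float],
                         rates_hz: Sequence[float]
                         ) -> Tuple[float, float, float, float]:
    """Least-squares line f = A·ϕ + B across bead diameters.

    Returns (A, B, se_A, se_B).  B estimates the zero-size (low-load)
    rotation rate.  Requires >= 3 distinct diameters.
    """
    d = np.asarray(diameters_nm, dtype=float)
    f = np.asarray(rates_hz, dtype=float)
    if len(np.unique(d)) < 3:
        raise IdentifiabilityError("need >= 3 distinct diameters")
    res = linregress(d, f)
    return (float(res.slope), float(res.intercept),
            float(res.stderr), float(res.intercept_stderr))
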