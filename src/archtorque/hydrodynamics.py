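"""Closed-form low-Reynolds-number drag coefficients for rotation-assay markers.

All drags are *rotational* drag coefficients about the motor axis, in
pN·nm·s, so that torque = γ · (angular velocity in rad/s).  Formulas:

sphere of radius r orbiting at rotation radius R:
    γ = 8πηr³ + 6πηrR²
(spin of the bead about its own centre plus translation of the centre
around the orbit).

sphere translating parallel to a plane wall, centre at height h:
    drag is increased by the method-of-reflections factor
    [1 − (9/16)(r/h) + (1/8)(r/h)³ − (45/256)(r/h)⁴ − (1/16)(r/h)⁵]⁻¹

rod of length L and cross-section radius r rotating about its centre
perpendicular to its axis:
    γ = (1/3)πηL³ [ln(L/2r) − 0.66]⁻¹
A tethered cell pivots about one end, which is equivalent to half a rod
of twice the length: ½γ evaluated at L = 2·(cell length).

helical filament (helix radius b, pitch p, contour length L, filament
cross-section radius r) rotating about its helix axis:
    γ = 2πηb²L (2p² + 4π²b²) (p² + 4π²b²)⁻¹ [ln(2p/r) − 0.5]⁻¹
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from . import markers as mk
from .errors import ParameterError
from .units import eta_internal


@dataclass(frozen=True)
class DragEstimate:
    """A drag coefficient with its (optional) wall correction.

    ``gamma`` is the free-space value in pN·nm·s; ``corrected`` is
    ``gamma * correction_factor`` (factor 1 when no correction applies).
    """

    gamma: float
    correction_factor: float = 1.0
    formula_id: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        if not self.gamma >= 0:
            raise ParameterError("drag coefficient must be non-negative")
        if self.correction_factor < 1.0:
            raise ParameterError("wall correction factor must be >= 1")

    @property
    def corrected(self) -> float:
        return self.gamma * self.correction_factor

    def as_dict(self) -> dict:
        return {
            "gamma_pn_nm_s": self.gamma,
            "correction_factor": self.correction_factor,
            "gamma_corrected_pn_nm_s": self.corrected,
            "formula_id": self.formula_id,
            "note": self.note,
        }


def sphere_drag(radius_nm: float, rotation_radius_nm: float,
                eta_pa_s: float) -> DragEstimate:
    """Rotational drag of a bead of radius ``radius_nm`` orbiting at
    ``rotation_radius_nm``: γ = 8πηr³ + 6πηrR²."""
    if radius_nm <= 0:
        raise ParameterError("bead radius must be positive")
    if rotation_radius_nm < 0:
        raise ParameterError("rotation radius must be non-negative")
    if eta_pa_s <= 0:
        raise ParameterError("viscosity must be positive")
    eta = eta_internal(eta_pa_s)
    gamma = (8.0 * math.pi * eta * radius_nm**3
             + 6.0 * math.pi * eta * radius_nm * rotation_radius_nm**2)
    return DragEstimate(gamma=gamma, formula_id="sphere_orbit")


def wall_correction(diameter_nm: float, gap_nm: float, order: int = 5) -> float:
    """Drag increase for a sphere translating parallel to a plane wall.

    ``gap_nm`` is the surface-to-surface gap; the wall distance used in
    the series is h = gap + r (sphere centre height).  The series is
    truncated at the (r/h)^5 term by default, which reproduces the
    factors 1.4, 1.2 and 1.1 for 1.0-, 0.49- and 0.21-µm beads at a
    0.5-µm gap at two significant figures.
    """
    if diameter_nm <= 0:
        raise ParameterError("diameter must be positive")
    if gap_nm < 0:
        raise ParameterError("gap must be non-negative")
    if order not in (1, 3, 4, 5):
        raise ParameterError("series order must be one of 1, 3, 4, 5")
    r = diameter_nm / 2.0
    h = gap_nm + r
    x = r / h
    terms = {1: -9.0 / 16.0 * x,
             3: x**3 / 8.0,
             4: -45.0 / 256.0 * x**4,
             5: -x**5 / 16.0}
    s = 1.0 + sum(v for k, v in terms.items() if k <= order)
    if s <= 0:
        raise ParameterError("wall-correction series diverged (sphere too close)")
    return 1.0 / s


def rod_drag_tethered(cell_length_nm: float, cell_radius_nm: float,
                      eta_pa_s: float) -> DragEstimate:
    """Drag of a rod-shaped cell pivoting about one end.

    Evaluates half the centre-pivot rod formula at L = 2·cell_length:
    ½ · (1/3)πηL³ [ln(L/2r) − 0.66]⁻¹.
    """
    if cell_length_nm <= 0 or cell_radius_nm <= 0:
        raise ParameterError("cell length and radius must be positive")
    if eta_pa_s <= 0:
        raise ParameterError("viscosity must be positive")
    L = 2.0 * cell_length_nm
    log_term = math.log(L / (2.0 * cell_radius_nm)) - 0.66
    if log_term <= 0:
        raise ParameterError(
            "rod drag undefined: ln(L/2r) - 0.66 <= 0 with L = 2*cell_length; "
            "the cell is not slender enough for the rod formula"
        )
    eta = eta_internal(eta_pa_s)
    gamma = 0.5 * (math.pi * eta * L**3 / 3.0) / log_term
    return DragEstimate(gamma=gamma, formula_id="rod_end_pivot")


def helix_drag(helix_radius_nm: float, pitch_nm: float, length_nm: float,
               filament_radius_nm: float, eta_pa_s: float,
               length_convention: str = "contour") -> DragEstimate:
    """Rotational drag of a helical filament about its helix axis.

    ``length_convention`` selects how ``length_nm`` is interpreted:
    ``"contour"`` (default) takes it as the contour length L entering
    the formula directly; ``"axial"`` takes it as the axial extent of
    the helix and converts to contour length by the factor
    sqrt(p² + 4π²b²)/p before evaluating.

    The degenerate straight-filament limit b → 0 gives γ → 0 (this
    closed form captures only the helical sweep, not axial spin).
    """
    b, p, r = helix_radius_nm, pitch_nm, filament_radius_nm
    if p <= 0 or r <= 0 or length_nm <= 0 or b < 0:
        raise ParameterError("helix parameters must be positive (b >= 0)")
    if eta_pa_s <= 0:
        raise ParameterError("viscosity must be positive")
    if length_convention not in ("contour", "axial"):
        raise ParameterError("length_convention must be 'contour' or 'axial'")
    log_term = math.log(2.0 * p / r) - 0.5
    if log_term <= 0:
        raise ParameterError("helix drag undefined: ln(2p/r) - 0.5 <= 0")
    wavelength_sq = p**2 + 4.0 * math.pi**2 * b**2
    L = length_nm
    if length_convention == "axial":
        L = length_nm * math.sqrt(wavelength_sq) / p
    eta = eta_internal(eta_pa_s)
    gamma = (2.0 * math.pi * eta * b**2 * L
             * (2.0 * p**2 + 4.0 * math.pi**2 * b**2) / wavelength_sq / log_term)
    note = (f"length interpreted as {length_convention} length; the two "
            "conventions differ by the factor sqrt(p^2+4pi^2 b^2)/p")
    if b == 0:
        note = "b = 0: straight filament, zero helical drag"
    return DragEstimate(gamma=gamma, formula_id="helix_axis", note=note)


def marker_drag(geometry: mk.MarkerGeometry, eta_pa_s: float,
                apply_wall_correction: bool = True) -> DragEstimate:
    """Dispatch drag calculation on marker kind.

    Spheres get the near-wall correction factor (applied to the full
    two-term γ); tethered cells do not (no correction is defined for
    them).  Helix markers are filaments, not orbit markers, and are
    rejected here — use :func:`helix_drag` directly.
    """
    geometry.validate()
    if geometry.kind == mk.SPHERE:
        est = sphere_drag(geometry.diameter_nm / 2.0,
                          geometry.rotation_radius_nm, eta_pa_s)
        factor = 1.0
        if apply_wall_correction:
            factor = wall_correction(geometry.diameter_nm, geometry.wall_gap_nm)
        return DragEstimate(gamma=est.gamma, correction_factor=factor,
                            formula_id=est.formula_id)
    if geometry.kind == mk.ROD:
        return rod_drag_tethered(geometry.cell_length_nm,
                                 geometry.cell_radius_nm, eta_pa_s)
    raise ParameterError("helix geometries are filaments, not load markers; "
                         "use helix_drag()")
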