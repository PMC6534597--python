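"""Unit conventions used throughout the package.

Lengths are in nm, times in s, energies and torques in pN·nm, drag
coefficients in pN·nm·s.  Viscosity is stored in Pa·s (the unit a
viscometer reports) and converted internally:

    1 Pa·s = 1 N·s·m⁻² = 10¹² pN · s / 10¹⁸ nm² = 10⁻⁶ pN·s·nm⁻²
"""

PA_S_TO_PN_S_PER_NM2 = 1e-6

#: Thermal energy at room temperature, pN·nm (k_B · 296 K ≈ 4.1).
KBT_ROOM = 4.1

#: Viscosity of the high-salt motility buffer, Pa·s.
ETA_BUFFER = 1.35e-3


def eta_internal(eta_pa_s: float) -> float:
    """Convert a viscosity in Pa·s to internal units (pN·s·nm⁻²)."""
    return eta_pa_s * PA_S_TO_PN_S_PER_NM2


def eta_pa_s(eta_int: float) -> float:
    """Inverse of :func:`eta_internal` (lossless round trip)."""
    return eta_int / PA_S_TO_PN_S_PER_NM2
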