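"""Marker geometries: beads, tethered cells and helical filaments.

A marker is whatever is attached to (or driven by) the motor and whose
viscous drag loads it: a polystyrene bead orbiting at some rotation
radius, a rod-shaped cell pivoting about one end in the tethered-cell
assay, or the helical filament itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .errors import ParameterError

SPHERE = "sphere"
ROD = "rod"
HELIX = "helix"

_KINDS = (SPHERE, ROD, HELIX)


@dataclass
class MarkerGeometry:
    """Geometry of a load marker.

    Only the fields relevant to ``kind`` need to be set.  Lengths in nm.

    sphere: ``diameter_nm``, ``rotation_radius_nm``, ``wall_gap_nm``
    rod (tethered cell): ``cell_length_nm``, ``cell_radius_nm``
    helix: ``helix_radius_nm``, ``pitch_nm``, ``length_nm``,
    ``filament_radius_nm``
    """

    kind: str
    diameter_nm: Optional[float] = None
    rotation_radius_nm: Optional[float] = None
    wall_gap_nm: float = 500.0
    cell_length_nm: Optional[float] = None
    cell_radius_nm: Optional[float] = None
    helix_radius_nm: Optional[float] = None
    pitch_nm: Optional[float] = None
    length_nm: Optional[float] = None
    filament_radius_nm: Optional[float] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.kind not in _KINDS:
            raise ParameterError(f"unknown marker kind {self.kind!r}")
        if self.kind == SPHERE:
            if self.diameter_nm is None or self.diameter_nm <= 0:
                raise ParameterError("sphere requires diameter_nm > 0")
            if self.rotation_radius_nm is None or self.rotation_radius_nm < 0:
                raise ParameterError("sphere requires rotation_radius_nm >= 0")
            if self.wall_gap_nm < 0:
                raise ParameterError("wall_gap_nm must be >= 0")
        elif self.kind == ROD:
            if self.cell_length_nm is None or self.cell_length_nm <= 0:
                raise ParameterError("rod requires cell_length_nm > 0")
            if self.cell_radius_nm is None or self.cell_radius_nm <= 0:
                raise ParameterError("rod requires cell_radius_nm > 0")
            # the rod drag formula needs ln(L/2r) - 0.66 > 0 with L = 2*length
            if 2.0 * self.cell_length_nm / (2.0 * self.cell_radius_nm) <= math.e**0.66:
                raise ParameterError(
                    "rod aspect ratio too small: need L/(2r) > e^0.66 with "
                    "L = 2*cell_length (log term of the rod drag formula)"
                )
        elif self.kind == HELIX:
            for name in ("helix_radius_nm", "pitch_nm", "length_nm", "filament_radius_nm"):
                v = getattr(self, name)
                if v is None or v <= 0:
                    raise ParameterError(f"helix requires {name} > 0")

    @property
    def orbit_radius_nm(self) -> float:
        """Radius of the circular orbit traced by the marker centroid.

        For a bead this is its rotation radius; for a tethered cell the
        far cell end orbits with lever arm equal to the cell length
        (pivot at the cell pole where the filament is attached).
        """
        if self.kind == SPHERE:
            return float(self.rotation_radius_nm)
        if self.kind == ROD:
            return float(self.cell_length_nm)
        raise ParameterError("helix markers have no centroid orbit")

    # -- convenience constructors -------------------------------------

    @classmethod
    def sphere(cls, diameter_nm: float, rotation_radius_nm: float,
               wall_gap_nm: float = 500.0) -> "MarkerGeometry":
        return cls(SPHERE, diameter_nm=diameter_nm,
                   rotation_radius_nm=rotation_radius_nm,
                   wall_gap_nm=wall_gap_nm)

    @classmethod
    def tethered_cell(cls, cell_length_nm: float,
                      cell_radius_nm: float = 250.0) -> "MarkerGeometry":
        return cls(ROD, cell_length_nm=cell_length_nm,
                   cell_radius_nm=cell_radius_nm)

    @classmethod
    def helix(cls, helix_radius_nm: float, pitch_nm: float, length_nm: float,
              filament_radius_nm: float) -> "MarkerGeometry":
        return cls(HELIX, helix_radius_nm=helix_radius_nm, pitch_nm=pitch_nm,
                   length_nm=length_nm, filament_radius_nm=filament_radius_nm)
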