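"""Optical model of the wedge-prism dual-spot 3D tracking scheme.

A wedge prism at the equivalent back focal plane splits the image of a
point source into two spots.  Their mean position encodes the lateral
(x, y) position; their separation along the prism axis encodes the
axial position z linearly:

    separation = baseline_separation + axial_gain · z

Image coordinates: origin at the top-left pixel centre, x rightward
(columns), y downward (rows), 0-based; z is positive away from the
coverslip.  Physical lateral nm are measured from the field-of-view
centre: ``x_nm = (x_px - (width-1)/2) * pixel_size`` and likewise for y.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import tifffile

from .errors import ParameterError


@dataclass
class OpticsParams:
    """Camera and prism parameters of the dual-spot tracking path."""

    pixel_size_nm: float = 98.0
    frame_interval_s: float = 5e-4
    psf_sigma_nm: float = 130.0
    prism_axis: Tuple[float, float] = (1.0, 0.0)
    prism_offset_nm: Tuple[float, float] = (0.0, 0.0)
    baseline_separation_nm: float = 1470.0
    axial_gain: float = 0.5
    photons_per_spot: float = 1e4
    read_noise_counts: float = 2.0
    camera_offset_counts: float = 100.0
    frame_shape: Tuple[int, int] = (48, 48)  # (rows, cols)

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ParameterError("pixel_size_nm must be positive")
        if self.psf_sigma_nm <= 0:
            raise ParameterError("psf_sigma_nm must be positive")
        if self.axial_gain == 0:
            raise ParameterError("axial_gain must be non-zero")
        norm = float(np.hypot(*self.prism_axis))
        if norm == 0:
            raise ParameterError("prism_axis must be a non-zero 2-vector")
        self.prism_axis = (self.prism_axis[0] / norm, self.prism_axis[1] / norm)

    @property
    def center_px(self) -> Tuple[float, float]:
        """(x, y) pixel coordinates mapped to lateral (0, 0) nm."""
        rows, cols = self.frame_shape
        return ((cols - 1) / 2.0, (rows - 1) / 2.0)

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_nm / self.pixel_size_nm

    def to_meta(self) -> dict:
        d = asdict(self)
        d["prism_axis"] = list(self.prism_axis)
        d["prism_offset_nm"] = list(self.prism_offset_nm)
        d["frame_shape"] = list(self.frame_shape)
        return d

    @classmethod
    def from_meta(cls, meta: dict) -> "OpticsParams":
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in meta.items() if k in known}
        for key in ("prism_axis", "prism_offset_nm", "frame_shape"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class ImageStack:
    """A multi-page 16-bit image stack plus its acquisition metadata.

    ``meta`` always records the pixel size, frame interval, axial
    calibration of the rendering optics and any renderer warnings
    (e.g. spot pairs closer than the separability threshold).
    """

    frames: np.ndarray  # (n, rows, cols) uint16
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ParameterError("frames must have shape (n, rows, cols)")

    def __len__(self) -> int:
        return self.frames.shape[0]

    def save(self, path: str | Path) -> None:
        """Write a multi-page TIFF with a JSON metadata sidecar."""
        path = Path(path)
        tifffile.imwrite(path, self.frames.astype(np.uint16))
        sidecar = path.with_suffix(path.suffix + ".json")
        with open(sidecar, "w", encoding="utf-8") as fh:
            json.dump(self.meta, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "ImageStack":
        path = Path(path)
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = {}
        if sidecar.exists():
            with open(sidecar, encoding="utf-8") as fh:
                meta = json.load(fh)
        return cls(frames=frames, meta=meta)

    def optics(self) -> OpticsParams:
        if "optics" not in self.meta:
            raise ParameterError("stack metadata carries no optics parameters")
        return OpticsParams.from_meta(self.meta["optics"])
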