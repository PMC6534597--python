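"""Time-stamped 3D marker trajectories and their CSV dialect.

The on-disk format is a plain UTF-8 CSV with header
``t_s,x_nm,y_nm,z_nm`` ('.' decimal separator).  Frames that failed
quality control downstream carry a per-frame flag; flagged frames may
hold NaN coordinates but are never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ParameterError

FLAG_OK = 0
FLAG_NO_SPOT = 1
FLAG_PAIRING = 2
FLAG_EDGE = 3


@dataclass
class Trajectory3D:
    """Positions (nm, shape ``(n, 3)``) sampled at times (s, shape ``(n,)``).

    ``flags`` holds one integer QC flag per frame (0 = good); ``meta``
    carries free-form provenance (simulation parameters, drag used, ...).
    """

    times: np.ndarray
    positions: np.ndarray
    flags: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ParameterError("positions must have shape (n, 3)")
        if self.times.shape[0] != self.positions.shape[0]:
            raise ParameterError("times and positions length mismatch")
        if self.flags is None:
            self.flags = np.zeros(len(self.times), dtype=int)
        else:
            self.flags = np.asarray(self.flags, dtype=int)
        if np.any(np.diff(self.times) <= 0):
            raise ParameterError("times must be strictly increasing")
        good = self.flags == FLAG_OK
        if not np.all(np.isfinite(self.positions[good])):
            raise ParameterError("non-finite coordinates on unflagged frames")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def good(self) -> np.ndarray:
        """Boolean mask of frames that passed QC."""
        return self.flags == FLAG_OK

    def good_positions(self) -> np.ndarray:
        return self.positions[self.good]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({
            "t_s": self.times,
            "x_nm": self.positions[:, 0],
            "y_nm": self.positions[:, 1],
            "z_nm": self.positions[:, 2],
        })
        if np.any(self.flags != FLAG_OK):
            df["flag"] = self.flags
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory3D":
        df = pd.read_csv(path)
        required = ["t_s", "x_nm", "y_nm", "z_nm"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ParameterError(f"trajectory CSV missing columns {missing}")
        flags = df["flag"].to_numpy() if "flag" in df.columns else None
        return cls(times=df["t_s"].to_numpy(),
                   positions=df[["x_nm", "y_nm", "z_nm"]].to_numpy(),
                   flags=flags)
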