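"""Pipeline configuration: YAML in, strict validation, stable hashing."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional

import yaml

from .errors import ConfigError

# allowed keys per config section; None means "scalar leaf"
_SCHEMA: Dict[str, Any] = {
    "seed": None,
    "version": None,
    "stages": {"simulate": None, "track": None, "analyze": None,
               "fit": None, "energetics": None},
    "motor": {"torque_pn_nm": None, "gamma_a_pn_nm_s": None, "mode": None,
              "f_noload_hz": None, "step_size_deg": None, "direction": None},
    "sim": {"dt_s": None, "duration_s": None, "k_bt_pn_nm": None,
            "eta_pa_s": None, "substeps": None},
    "markers": "list",
    "optics": {"pixel_size_nm": None, "frame_interval_s": None,
               "psf_sigma_nm": None, "prism_axis": "list",
               "prism_offset_nm": "list", "baseline_separation_nm": None,
               "axial_gain": None, "photons_per_spot": None,
               "read_noise_counts": None, "camera_offset_counts": None,
               "frame_shape": "list"},
    "qc": {"period_deg": None, "depth_threshold": None, "dwell_factor": None},
    "fit": {"variant": None, "n_bootstrap": None,
            "apply_wall_correction": None},
    "energetics": {"delta_g_atp": None, "n_max": None, "tolerance": None},
}

_MARKER_KEYS = {"kind", "n", "diameter_nm", "rotation_radius_nm",
                "wall_gap_nm", "cell_length_nm", "cell_radius_nm"}

DEFAULT_CONFIG: Dict[str, Any] = {
    "seed": 0,
    "stages": {"simulate": True, "track": False, "analyze": True,
               "fit": True, "energetics": True},
    "motor": {"torque_pn_nm": 160.0, "gamma_a_pn_nm_s": 0.81,
              "mode": "model_A", "direction": "CCW"},
    "sim": {"dt_s": 5e-4, "duration_s": 4.0},
    "markers": [
        {"kind": "sphere", "n": 2, "diameter_nm": 210.0,
         "rotation_radius_nm": 250.0},
        {"kind": "sphere", "n": 2, "diameter_nm": 490.0,
         "rotation_radius_nm": 250.0},
        {"kind": "sphere", "n": 2, "diameter_nm": 1000.0,
         "rotation_radius_nm": 250.0},
        {"kind": "rod", "n": 2, "cell_length_nm": 2000.0,
         "cell_radius_nm": 250.0},
    ],
    "optics": {},
    "qc": {},
    "fit": {"variant": "corrected", "n_bootstrap": 200,
            "apply_wall_correction": True},
    "energetics": {"delta_g_atp": 80.0, "n_max": 6, "tolerance": 0.10},
}


def _check_keys(cfg: Any, schema: Any, path: str = "") -> None:
    if schema is None or schema == "list":
        return
    if not isinstance(cfg, dict):
        raise ConfigError(f"section {path or '<root>'} must be a mapping")
    for key, value in cfg.items():
        if key not in schema:
            raise ConfigError(f"unknown config key {path + key!r}")
        sub = schema[key]
        if isinstance(sub, dict):
            _check_keys(value, sub, path + key + ".")
    if "markers" in cfg:
        for i, m in enumerate(cfg["markers"]):
            extra = set(m) - _MARKER_KEYS
            if extra:
                raise ConfigError(f"unknown marker keys {sorted(extra)} "
                                  f"in markers[{i}]")


def _merge(base: Dict[str, Any], override: Dict[str, Any]) -> Dict[str, Any]:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration (defaults merged with user YAML)."""

    data: Dict[str, Any] = field(default_factory=lambda: dict(DEFAULT_CONFIG))

    def __post_init__(self) -> None:
        _check_keys(self.data, _SCHEMA)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        _check_keys(user, _SCHEMA)
        return cls(data=_merge(DEFAULT_CONFIG, user))

    def __getitem__(self, key: str) -> Any:
        return self.data[key]

    def resolved_yaml(self) -> str:
        return yaml.safe_dump(self.data, sort_keys=True)

    @property
    def hash(self) -> str:
        """Short stable hash of the resolved configuration."""
        return hashlib.sha256(self.resolved_yaml().encode()).hexdigest()[:12]

    def dump(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.resolved_yaml())
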