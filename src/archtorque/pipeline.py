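"""End-to-end pipeline: simulate → (render/track) → analyze → fit → energetics.

One invocation writes one run directory containing the resolved config
snapshot, per-trajectory analysis records, the marker table, torque
fits (raw and corrected), the energetics report, and a stage log.
Every JSON output names the config hash that produced it; outputs are
byte-identical across reruns with the same config and seed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import markers as mk
from .config import PipelineConfig
from .energetics import energetics_report
from .errors import ArchTorqueError, GeometryError
from .geometry import analyze_trajectory
from .optics import OpticsParams
from .synthetic import (MotorParams, PlaneSpec, SimParams,
                        render_dual_image_stack, simulate_rotation_trace)
from .torque import (MarkerRecord, apparent_torque_curve, fit_constant_torque,
                     marker_friction)
from .tracking import AxialCalibration, reconstruct_3d
from .trajectory import Trajectory3D


def _write_json(path: Path, payload: dict, config_hash: str) -> None:
    payload = {"config_hash": config_hash, **payload}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")


def _marker_list(cfg: PipelineConfig) -> List[mk.MarkerGeometry]:
    out = []
    for spec in cfg["markers"]:
        n = int(spec.get("n", 1))
        for _ in range(n):
            if spec["kind"] == "sphere":
                out.append(mk.MarkerGeometry.sphere(
                    spec["diameter_nm"], spec["rotation_radius_nm"],
                    wall_gap_nm=spec.get("wall_gap_nm", 500.0)))
            elif spec["kind"] == "rod":
                out.append(mk.MarkerGeometry.tethered_cell(
                    spec["cell_length_nm"], spec.get("cell_radius_nm", 250.0)))
            else:
                raise ArchTorqueError(f"unsupported marker kind {spec['kind']!r}")
    return out


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the enabled stages; returns the run directory.

    Stages are skippable through ``config['stages']``; a run with no
    stage enabled is a warning no-op.  Failures leave partial outputs
    plus a ``FAILED`` marker naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash
    log: List[str] = [f"config_hash {chash}"]
    config.dump(out / "config_resolved.yaml")
    stages = config["stages"]
    if not any(stages.values()):
        log.append("warning: no stages enabled; no-op")
    try:
        _run_stages(config, out, chash, log)
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        log.append(f"FAILED {type(exc).__name__}: {exc}")
        raise
    finally:
        (out / "log.txt").write_text("\n".join(log) + "\n")
    return out


def _run_stages(config: PipelineConfig, out: Path, chash: str,
                log: List[str]) -> None:
    stages = config["stages"]
    seed = int(config["seed"])
    ss = np.random.SeedSequence(seed)
    motor = MotorParams(**config["motor"])
    optics = OpticsParams(**{k: tuple(v) if isinstance(v, list) else v
                             for k, v in config["optics"].items()})
    eta = config["sim"].get("eta_pa_s", SimParams().eta_pa_s)

    trajectories: List[Trajectory3D] = []
    geometries: List[mk.MarkerGeometry] = []

    if stages.get("simulate"):
        traj_dir = out / "trajectories"
        traj_dir.mkdir(exist_ok=True)
        markers_list = _marker_list(config)
        child_seeds = ss.spawn(len(markers_list))
        for i, (geom, cs) in enumerate(zip(markers_list, child_seeds)):
            sub_seed = int(cs.generate_state(1)[0] % (2**31))
            rng = np.random.default_rng(sub_seed)
            plane = PlaneSpec(theta_deg=float(rng.uniform(10, 60)),
                              phi_deg=float(rng.uniform(0, 360)),
                              center_nm=(0.0, 0.0, 500.0))
            sim = SimParams(seed=sub_seed, **config["sim"])
            traj = simulate_rotation_trace(motor, geom, plane, sim)
            if stages.get("track"):
                stack = render_dual_image_stack(traj, optics,
                                                seed=sub_seed + 1)
                calib = AxialCalibration.from_optics(optics)
                tracked = reconstruct_3d(stack, calib, optics)
                # keep simulated z-offset out of the comparison: tracking
                # reports absolute z, simulation used the plane centre
                traj = tracked
            traj.to_csv(traj_dir / f"traj_{i:03d}.csv")
            trajectories.append(traj)
            geometries.append(geom)
        log.append(f"simulate: {len(trajectories)} trajectories"
                   + (" (image round-trip)" if stages.get("track") else ""))

    records: List[MarkerRecord] = []
    if stages.get("analyze") and trajectories:
        rec_dir = out / "analysis"
        rec_dir.mkdir(exist_ok=True)
        n_rejected = 0
        for i, (traj, geom) in enumerate(zip(trajectories, geometries)):
            try:
                record = analyze_trajectory(traj, qc_kwargs=config["qc"])
            except GeometryError as exc:
                log.append(f"analyze traj_{i:03d}: skipped ({exc})")
                continue
            _write_json(rec_dir / f"traj_{i:03d}.json", record, chash)
            accepted = record["qc"]["accepted"]
            n_rejected += not accepted
            rec = MarkerRecord(marker_id=f"traj_{i:03d}", geometry=geom,
                               rate_hz=record["rate"]["rate_hz"],
                               rate_se_hz=record["rate"]["rate_se_hz"],
                               qc_accepted=accepted)
            records.append(marker_friction(
                rec, eta,
                apply_wall_correction=config["fit"]["apply_wall_correction"]))
            log.append(f"analyze traj_{i:03d}: rate "
                       f"{record['rate']['rate_hz']:.3g} Hz, "
                       f"qc={'accepted' if accepted else 'rejected'} "
                       f"({record['qc']['reason']})")
        if records:
            pd.DataFrame([{
                "marker_id": r.marker_id, "kind": r.geometry.kind,
                "rate_hz": r.rate_hz, "gamma_raw": r.gamma_raw,
                "gamma_corrected": r.gamma_corrected,
                "qc_accepted": r.qc_accepted,
            } for r in records]).to_csv(out / "records.csv", index=False)
        log.append(f"analyze: {len(records)} records, {n_rejected} rejected")

    fit = None
    if stages.get("fit") and records:
        fits = {}
        for variant in ("raw", "corrected"):
            fits[variant] = fit_constant_torque(
                records, variant=variant,
                n_bootstrap=int(config["fit"]["n_bootstrap"]), seed=seed)
        fit = fits[config["fit"]["variant"]]
        _write_json(out / "torque_fit.json",
                    {v: f.as_dict() for v, f in fits.items()}, chash)
        curve = apparent_torque_curve(records, fit)
        curve.to_csv(out / "apparent_torque.tsv", sep="\t", index=False)
        log.append(f"fit: T_a={fit.torque_pn_nm:.4g} pN·nm, "
                   f"gamma_a={fit.gamma_a_pn_nm_s:.3g} pN·nm·s "
                   f"({fit.variant})")

    if stages.get("energetics") and fit is not None:
        en = config["energetics"]
        report = energetics_report(fit.torque_pn_nm,
                                   delta_g_atp=en["delta_g_atp"],
                                   n_max=int(en["n_max"]),
                                   tolerance=en["tolerance"])
        _write_json(out / "energetics.json", report.as_dict(), chash)
        log.append(f"energetics: W={report.work_per_rotation_pn_nm:.4g} "
                   f"pN·nm, feasible n={report.feasible_n}")
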