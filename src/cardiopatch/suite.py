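"""Scenario-suite driver: run the enumerated remodeling scenarios and
collect the summary statistics (irregularity, CV, heterogeneity, AF flag).

Each scenario/seed run writes one HDF5 result file named by its config
hash; reruns skip scenarios whose result file already exists (resumable).
A ``summary.csv`` aggregates one row per scenario/seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, io, protocols, remodeling, tissue

log = logging.getLogger("cardiopatch.suite")

__all__ = ["run_scenario_suite"]


def _scenario_hash(cfg: dict, scenario, seed: int) -> str:
    payload = json.dumps(
        {"cfg": cfg, "scenario": scenario.to_json(), "seed": seed},
        sort_keys=True, default=str,
    )
    return hashlib.sha1(payload.encode()).hexdigest()[:16]


def _analyze(res, grid, scenario, seed):
    row = {
        "scenario": scenario.name,
        "seed": seed,
        "failed": res.failed,
        "irregularity_pct": np.nan,
        "mean_rate_bpm": np.nan,
        "cv_cm_s": np.nan,
        "heterogeneity": np.nan,
        "sustained_af": False,
    }
    if res.failed:
        return row
    try:
        irr = analysis.tissue_irregularity(res.activation)
        row["irregularity_pct"] = irr.irregularity
        row["mean_rate_bpm"] = irr.mean_rate
    except ValueError:
        pass
    counts = res.activation.counts()
    if counts.max() >= 1:
        beat = int(min(1, counts.max() - 1))
        field = analysis.conduction_field(res.activation, beat, grid.dx)
        if field.valid.sum() >= 2:
            row["cv_cm_s"] = float(np.nanmedian(field.speed[field.valid]))
            row["heterogeneity"] = analysis.heterogeneity_index(field)
    return row


def run_scenario_suite(cfg, out_dir) -> Path:
    """Execute the configured scenario suite; returns the results directory.

    Partial failures are logged and recorded; the suite continues.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_d = cfg.to_dict() if hasattr(cfg, "to_dict") else dict(cfg)
    rows = []
    n_failed = 0

    if cfg_d["kind"] == "hipsc_suite":
        scenarios = remodeling.enumerate_hipsc_scenarios(
            intensities=tuple(cfg_d["intensities"]),
            patch_radius=cfg_d["patch_radius_cm"],
        )
    else:
        scenarios = remodeling.enumerate_atria_configs(
            patch_radius=cfg_d["patch_radius_cm"],
        )

    base_d = cfg_d.get("base_diffusivity")
    if base_d is None:
        base_d = protocols.calibrate_conductivity(
            cfg_d["model_id"], cfg_d.get("target_cv"),
        )
        log.info("calibrated base diffusivity: %.4g cm^2/ms", base_d)

    for scenario in scenarios:
        seeds = cfg_d["seeds"] if scenario.name != "control" else cfg_d["seeds"][:1]
        for seed in seeds:
            h = _scenario_hash(cfg_d, scenario, seed)
            path = out / f"{scenario.name}_s{seed}_{h}.h5"
            if path.exists():
                log.info("skip completed %s (seed %s)", scenario.name, seed)
                continue
            log.info("run %s seed=%s", scenario.name, seed)
            try:
                if cfg_d["kind"] == "hipsc_suite":
                    grid = tissue.build_square_tissue(
                        cfg_d["nx"], cfg_d["ny"], dx_um=cfg_d["dx_cm"] * 1e4,
                        base_diffusivity=base_d, model_id=cfg_d["model_id"],
                    )
                    remodeling.scenario_remodeling(
                        grid, scenario, cfg_d["coverage"], seed=seed,
                    )
                    proto = protocols.spontaneous_protocol(cfg_d["duration_ms"])
                else:
                    grid = tissue.build_pseudo_atria(tissue.PseudoAtriaConfig(
                        nx=cfg_d["nx"], ny=cfg_d["ny"],
                        dx_um=cfg_d["dx_cm"] * 1e4, base_diffusivity=base_d,
                    ))
                    masks = remodeling.atria_region_masks(grid, scenario)
                    remodeling.scenario_remodeling(
                        grid, scenario, cfg_d["coverage"], seed=seed,
                        region_masks=masks or None,
                    )
                    proto = protocols.stress_pacing_protocol()
                res = tissue.run_tissue(
                    grid, proto, seed=seed,
                    output_spec=tissue.OutputSpec(frame_dt=cfg_d["frame_dt_ms"]),
                )
                row = _analyze(res, grid, scenario, seed)
                if cfg_d["kind"] == "atria_suite":
                    sustained, _ = analysis.detect_sustained_activity(
                        res.activation, proto.last_pulse_time,
                        window=min(2000.0, proto.duration - proto.last_pulse_time - 100),
                    )
                    row["sustained_af"] = bool(sustained)
                io.save_result(path, res, metrics={
                    k: v for k, v in row.items() if isinstance(v, (int, float, bool))
                })
            except Exception as exc:  # noqa: BLE001 - suite must continue
                log.error("scenario %s seed %s failed: %s", scenario.name, seed, exc)
                row = {"scenario": scenario.name, "seed": seed, "failed": True}
                n_failed += 1
            rows.append(row)
        log.info("finished scenario %s", scenario.name)

    summary = out / "summary.csv"
    df = pd.DataFrame(rows)
    if summary.exists():
        df = pd.concat([pd.read_csv(summary), df], ignore_index=True)
        df = df.drop_duplicates(subset=["scenario", "seed"], keep="last")
    df.to_csv(summary, index=False)
    if n_failed:
        raise RuntimeError(f"{n_failed} scenario run(s) failed; see log")
    return out
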