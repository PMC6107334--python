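"""Orchestration: reproducible end-to-end runs from a single config.

A run config (YAML or dict) names an input source — either a simulation block
mirroring :class:`~dcmorph.simulate.SimulationConfig` or paths to track/scene
files — plus analysis switches and parameters.  Stages execute in dependency
order (drift correction before metrics, metrics before circular tests); every
statistical test in the summary carries its method note and seed.  The same
config and seed give byte-identical JSON summaries.

The per-stage random streams are derived independently from the global seed,
so inserting or removing a stage never perturbs another stage's randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import circstats, spatial, tracks as trk
from .io import write_tracks
from .simulate import SimulationConfig, simulate_condensation

logger = logging.getLogger("dcmorph")

# fixed stage indices so per-stage seeds are independent of execution order
_STAGE_STREAMS = {"simulate": 0, "directionality": 1, "density": 2,
                  "neighbors": 3, "cycle_fractions": 4, "shape": 5}

DEFAULT_PARAMS = {
    "entry_radius": 15.0,       # µm; condensate entry for track truncation
    "distance_threshold": 30.0,  # µm; far/near split (average DC diameter)
    "truncate_at_entry": True,
    "n_permutations": 999,
    "n_mc": 2000,
    "signature_alpha": 0.01,    # stricter than 0.05: two signatures screened
    "paired_if_offset": (45.0, 0.0, 0.0),  # clone DC sphere here for control
}


def _stage_seed(global_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([int(global_seed), _STAGE_STREAMS[stage]])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def load_run_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("run config must be a mapping")
    return cfg


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages and return (and optionally write) a
    machine-readable summary.

    Config keys: ``seed`` (int), ``simulate`` (SimulationConfig fields, with
    optional ``preset``) or ``inputs`` (``tracks`` path), ``analyses`` (list
    of stage names), ``params`` (overrides of :data:`DEFAULT_PARAMS`).
    """
    seed = int(config.get("seed", 0))
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    analyses = config.get("analyses",
                          ["directionality", "density", "cycle_fractions"])
    summary: dict = {"config_hash": hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16],
        "seed": seed, "params": {k: (list(v) if isinstance(v, tuple) else v)
                                 for k, v in params.items()},
        "units": "lengths in um, times in min, angles in degrees",
        "stages": {}}

    scenes = None
    dc_center = None
    if "simulate" in config:
        sim_kwargs = dict(config["simulate"])
        preset = sim_kwargs.pop("preset", None)
        sim_kwargs.setdefault("seed", _stage_seed(seed, "simulate"))
        if preset is not None:
            sim_kwargs.pop("mode", None)
            sim_cfg = SimulationConfig.preset(preset, **sim_kwargs)
        else:
            sim_cfg = SimulationConfig(**sim_kwargs)
        logger.info("simulating mode=%s seed=%d", sim_cfg.mode, sim_cfg.seed)
        table, scenes = simulate_condensation(sim_cfg)
        dc_center = sim_cfg.dc_center
        summary["stages"]["simulate"] = {
            "mode": sim_cfg.mode, "n_cells": sim_cfg.n_cells,
            "n_frames": sim_cfg.n_frames, "seed": sim_cfg.seed,
            "n_tracks": int(table["track_id"].nunique())}
    elif "inputs" in config:
        from .io import read_tracks
        table = read_tracks(config["inputs"]["tracks"])
        dc_center = config["inputs"].get("dc_center")
        if dc_center is None:
            raise ValueError("inputs require an explicit dc_center")
    else:
        raise ValueError("config needs a 'simulate' block or 'inputs' paths")

    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        write_tracks(table, out_dir / "tracks.csv")

    if "directionality" in analyses:
        summary["stages"]["directionality"] = _directionality_stage(
            table, dc_center, params, seed, out_dir)
    final_scene = scenes[-1] if scenes else None
    if "density" in analyses and final_scene is not None:
        rep = spatial.region_density(
            final_scene, ["dc"], paired_clone=("dc", params["paired_if_offset"]))
        summary["stages"]["density"] = {
            "unit": rep.unit,
            "regions": rep.table.to_dict(orient="records"),
            "dc_over_paired_if": rep.ratios.get("dc/dc_paired")}
    if "cycle_fractions" in analyses and final_scene is not None:
        enr = spatial.marker_enrichment_test(
            final_scene, "fucci_sgm", "dc", alternative="greater")
        frac = spatial.fucci_fractions(final_scene, region="dc")
        summary["stages"]["cycle_fractions"] = {
            "dc": frac, "enrichment_test": enr.summary(),
            "proliferation_signature":
                bool(enr.p_value < params["signature_alpha"])}
    if "neighbors" in analyses and final_scene is not None and \
            "lineage" in final_scene.cells.columns and \
            final_scene.cells["lineage"].any():
        rep = spatial.nearest_neighbor_labels(
            final_scene, "dc_candidate", "dc_candidate", "lineage")
        test = spatial.neighbor_randomness_test(rep)
        summary["stages"]["neighbors"] = {
            "prop_labeled_neighbor": rep.prop_labeled,
            "expected_prop": rep.expected_prop, "n_focal": rep.n_focal,
            "test": test.summary()}

    summary["signatures"] = _signatures(summary, params)
    if out_dir is not None:
        (out_dir / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True, default=_jsonable))
        (out_dir / "report.txt").write_text(render_report(summary))
    return summary


def _directionality_stage(table: pd.DataFrame, dc_center, params: dict,
                          seed: int, out_dir: Path | None) -> dict:
    has_refs = (table["cell_class"] == "reference").any()
    corrected = trk.correct_drift(table) if has_refs else table
    metrics = trk.compute_track_metrics(
        corrected, center=dc_center,
        entry_radius=params["entry_radius"],
        truncate=params["truncate_at_entry"],
        threshold=params["distance_threshold"])
    if out_dir is not None:
        metrics.to_csv(out_dir / "track_metrics.csv", index=False)
    groups = trk.group_by_initial_distance(metrics,
                                           params["distance_threshold"])
    st_seed = _stage_seed(seed, "directionality")
    out: dict = {"drift_corrected": bool(has_refs), "groups": {}}
    angle_samples = {}
    for name, sub in groups.items():
        ang = sub["escape_angle_deg"].dropna().to_numpy()
        g = {"n": int(len(sub)), "n_angles": int(len(ang))}
        for col in ("velocity", "net_velocity", "straightness"):
            vals = sub[col].dropna()
            if len(vals):
                g[f"median_{col}"] = float(vals.median())
        if len(ang) >= 4:
            sample = circstats.AngleSample(ang, "axial_magnitude")
            angle_samples[name] = sample
            g["median_escape_angle_deg"] = float(np.median(ang))
            res = circstats.sphere_uniformity_test(
                sample, n_mc=params["n_mc"], seed=st_seed)
            g["sphere_uniformity_test"] = res.summary()
            g["inward_bias"] = bool(res.p_value < params["signature_alpha"]
                                    and res.statistic > 0)
        out["groups"][name] = g
    if "dc_far" in angle_samples and "interfollicular" in angle_samples:
        s1, s2 = angle_samples["dc_far"], angle_samples["interfollicular"]
        if s1.n >= 8 and s2.n >= 8:
            res = circstats.watson_u2_test(
                s1, s2, n_permutations=params["n_permutations"], seed=st_seed)
            out["watson_u2_dc_far_vs_if"] = res.summary()
    return out


def _signatures(summary: dict, params: dict) -> dict:
    sig = {"directed_migration_dc_far": None,
           "directed_migration_interfollicular": None,
           "proliferation": None}
    d = summary["stages"].get("directionality")
    if d:
        far = d["groups"].get("dc_far", {})
        iff = d["groups"].get("interfollicular", {})
        if "inward_bias" in far:
            sig["directed_migration_dc_far"] = far["inward_bias"]
        if "inward_bias" in iff:
            sig["directed_migration_interfollicular"] = iff["inward_bias"]
    c = summary["stages"].get("cycle_fractions")
    if c:
        sig["proliferation"] = c["proliferation_signature"]
    return sig


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def render_report(summary: dict) -> str:
    """Human-readable report: every statistical test with its method note."""
    lines = ["dcmorph analysis report",
             f"conventions: {summary['units']}",
             f"seed: {summary['seed']}   config: {summary['config_hash']}",
             ""]
    for stage, content in summary["stages"].items():
        lines.append(f"[{stage}]")
        lines.extend(_render(content, indent=2))
        lines.append("")
    lines.append("[signatures]")
    for k, v in summary.get("signatures", {}).items():
        lines.append(f"  {k}: {v}")
    return "\n".join(lines) + "\n"


def _render(obj, indent: int) -> list[str]:
    pad = " " * indent
    out = []
    if isinstance(obj, dict):
        for k, v in obj.items():
            if isinstance(v, (dict, list)):
                out.append(f"{pad}{k}:")
                out.extend(_render(v, indent + 2))
            else:
                out.append(f"{pad}{k}: {v}")
    elif isinstance(obj, list):
        for v in obj:
            out.extend(_render(v, indent))
    else:
        out.append(f"{pad}{obj}")
    return out
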