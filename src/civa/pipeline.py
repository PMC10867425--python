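"""Orchestration of the predict -> mimic -> stratify framework.

A run config names the stages to execute; each stage reads the previous
stage's declared outputs from the run directory. A :class:`RunManifest`
snapshotting the config, seed and input hashes is written alongside, and
every default the method leaves open (threshold method, ring geometry, T0
mode, denominator convention) is recorded in the manifest config so two
runs are comparable.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import quantify, simulate, stackio, timing, tracking, variants

__all__ = ["run_pipeline", "stratify"]

_STAGES = ("simulate", "quantify", "track", "timing", "screen")


def stratify(
    condition_ratios: dict[str, "pd.Series | np.ndarray"],
    control: str,
    impaired_fraction: float = 0.8,
) -> pd.DataFrame:
    """Label conditions whose kinetochore enrichment collapses.

    A condition is called ``localization-impaired`` when its median
    kinetochore/cytoplasm ratio falls below ``impaired_fraction`` of the
    control median; the Mann-Whitney p value against control is reported
    alongside.
    """
    ctrl = np.asarray(condition_ratios[control], dtype=float)
    rows = []
    for cond, vals in condition_ratios.items():
        vals = np.asarray(vals, dtype=float)
        if cond == control:
            rows.append({"condition": cond, "median_ratio": float(np.median(vals)),
                         "p_vs_control": None, "call": "control"})
            continue
        _, p = timing.compare_groups(vals, ctrl, test="mann_whitney")
        impaired = np.median(vals) < impaired_fraction * np.median(ctrl)
        rows.append(
            {"condition": cond, "median_ratio": float(np.median(vals)),
             "p_vs_control": p,
             "call": "localization-impaired" if impaired and p < 0.05 else "normal"}
        )
    return pd.DataFrame(rows)


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute the configured stages in order; returns output paths.

    Config keys: ``stages`` (ordered list), ``seed``, plus per-stage
    sections (``simulate``, ``quantify``, ``track``, ``timing``,
    ``screen``). Raises if a stage needs an upstream output that no prior
    stage produced.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", [])
    unknown = [s for s in stages if s not in _STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; valid: {_STAGES}")
    seed = int(config.get("seed", 0))
    produced: dict[str, Path] = {}

    for stage in stages:
        section = dict(config.get(stage, {}))
        if stage == "simulate":
            cfg = simulate.ImageSimConfig(**{**section, "seed": seed})
            stack, truth = simulate.sim_image_stack(cfg)
            stack_path = out / "stack.ome.tif"
            stackio.write_stack(stack, stack_path)
            truth.spots.to_csv(out / "truth_spots.csv", index=False)
            truth.pairs.to_csv(out / "truth_pairs.csv", index=False)
            produced["stack"] = stack_path
            produced["sim_config"] = cfg  # in-memory, for calibration reuse
        elif stage == "quantify":
            if "stack" not in produced:
                stack_in = section.pop("input", None)
                if stack_in is None:
                    raise ValueError("stage 'quantify' needs a stack: run 'simulate' first or set quantify.input")
                stack = stackio.read_stack(stack_in, **section.pop("read", {}))
            else:
                stack = stackio.read_stack(produced["stack"],
                                           channel_names=["CENPB", "YFP"],
                                           reference_channel="CENPB",
                                           measurement_channel="YFP")
            df = quantify.quantify_stack(
                stack,
                detect_cfg=quantify.DetectConfig(**section.get("detect", {})),
                ring_cfg=quantify.RingConfig(**section.get("ring", {})),
                subtract_background=section.get("subtract_background", True),
            )
            path = out / "measurements.csv"
            df.to_csv(path, index=False)
            produced["measurements"] = path
            produced["pixel_size_um"] = stack.pixel_size_um
            produced["frame_interval_min"] = stack.frame_interval_min
        elif stage == "track":
            if "measurements" not in produced:
                raise ValueError("stage 'track' needs 'quantify' outputs")
            df = pd.read_csv(produced["measurements"])
            frames = []
            for t in sorted(df.frame.unique()):
                frames.append(df[df.frame == t][["y_px", "x_px"]].to_numpy())
            tracks = tracking.link_particles(frames, section.get("max_disp_px", 5.0))
            tracking.tracks_table(tracks).to_csv(out / "tracks.csv", index=False)
            px = produced.get("pixel_size_um", section.get("pixel_size_um", 0.1))
            pairs = tracking.pair_trajectories(
                tracks, px,
                section.get("d_min_um", 0.5), section.get("d_max_um", 2.5),
            )
            series = [
                tracking.normalize_T0(
                    tracking.intercentromere_series(p, px, pair_id=i),
                    mode=section.get("t0_mode", "min"),
                )
                for i, p in enumerate(pairs)
                if len(set(p[0].frames) & set(p[1].frames)) >= 2
            ]
            pair_rows = []
            for s in series:
                for f, d, n in zip(s.frames, s.d_um, s.n):
                    pair_rows.append({"pair_id": s.pair_id, "frame": f, "d_um": d, "n": n})
            pd.DataFrame(pair_rows, columns=["pair_id", "frame", "d_um", "n"]).to_csv(
                out / "pairs.csv", index=False)
            summary = tracking.stretch_summary(
                series, produced.get("frame_interval_min", 6.0))
            summary.to_csv(out / "stretch_summary.tsv", sep="\t", index=False)
            produced["stretch_summary"] = out / "stretch_summary.tsv"
        elif stage == "timing":
            events_in = section.get("input")
            if events_in is None:
                raise ValueError("stage 'timing' needs timing.input (events CSV)")
            records = timing.read_events(events_in)
            summary = timing.timing_summary(
                records, completers_only=section.get("completers_only", False))
            summary.to_csv(out / "timing_summary.tsv", sep="\t", index=False)
            produced["timing_summary"] = out / "timing_summary.tsv"
        elif stage == "screen":
            table_in = section.get("input")
            if table_in is None:
                raise ValueError("stage 'screen' needs screen.input (variant table)")
            records = variants.read_variant_table(table_in)
            merged_inputs: dict[str, list] = {}
            for rec in records:
                ((src, _),) = rec.counts.items()
                merged_inputs.setdefault(src, []).append(rec)
            merged = variants.merge_databases(sorted(merged_inputs.items()))
            cands = variants.civa_filter(
                merged,
                min_individuals=section.get("min_individuals", 2),
                sum_sources=section.get("sum_sources", False),
            )
            variants.candidates_table(cands).to_csv(
                out / "candidates.tsv", sep="\t", index=False)
            produced["candidates"] = out / "candidates.tsv"

    manifest_cfg = {k: v for k, v in config.items()}
    manifest_cfg.setdefault("defaults", {
        "threshold_method": "otsu", "ring": dataclasses.asdict(quantify.RingConfig()),
        "t0_mode": "min", "t50_denominator": "all-cells",
    })
    manifest = stackio.RunManifest.create(
        _jsonable(manifest_cfg),
        inputs={k: v for k, v in produced.items()
                if isinstance(v, Path) and v.exists()},
        seed=seed,
    )
    manifest.write(out / "manifest.json")
    return {k: (str(v) if isinstance(v, Path) else v) for k, v in produced.items()}


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    try:
        json.dumps(obj)
        return obj
    except TypeError:
        return str(obj)
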