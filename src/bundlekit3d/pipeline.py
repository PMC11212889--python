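"""Batch pipeline orchestration: simulate/load → reconstruct → measure →
intensity → rows → texture → evaluate, one output folder per sample.

Per-sample failures are isolated: the batch continues and the summary lists
which samples failed and why.  Re-running the same configuration and seed
reproduces byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import traceback
from pathlib import Path

import pandas as pd

from . import evaluate, intensity, morphometry, phantoms, reconstruct, rows, stackio, texture

log = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "voxel_size": [0.110, 0.043, 0.043],
    "seed": 0,
    "stages": {
        "reconstruct": True,
        "measure": True,
        "intensity": True,
        "rows": True,
        "texture": True,
        "evaluate": True,
    },
    "reconstruct": {"min_overlap": 1, "max_gap": 0, "min_frames": 2, "min_voxels": 20},
    "rows": {"method": "gmm", "k": 4},
    "intensity": {"mode": 1, "subtract_background": False},
    "samples": [],
}


def run_sample(
    stack: stackio.ZStack,
    series: stackio.FrameMaskSeries,
    out_dir: Path,
    config: dict,
    gt_labels: stackio.LabelVolume | None = None,
) -> dict:
    """Run every enabled stage on one sample; returns a result summary."""
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = config["stages"]
    voxel = tuple(config["voxel_size"])
    tables: dict[str, pd.DataFrame] = {}

    rc = config["reconstruct"]
    vol = reconstruct.reconstruct_volume(
        series,
        shape=stack.shape,
        min_overlap=rc["min_overlap"],
        max_gap=rc["max_gap"],
        min_frames=rc["min_frames"],
        min_voxels=rc["min_voxels"],
    )
    stackio.write_label_volume(vol, out_dir / "labels.tif")

    heights = None
    if stages.get("measure", True):
        tables["measurements"] = morphometry.region_measurements(vol, voxel)
        heights = morphometry.measure_heights(vol, voxel)
        tables["heights"] = heights
        tables["orientation"] = morphometry.measure_orientations(vol)

    assignment = None
    if stages.get("rows", True) and heights is not None and len(heights) >= config["rows"]["k"]:
        assignment = rows.row_assign(
            heights, method=config["rows"]["method"], k=config["rows"]["k"], seed=config["seed"]
        )
        tables["rows"] = assignment.as_frame()
        tables["heights"] = heights.merge(assignment.as_frame(), on="id", how="left")

    if stages.get("intensity", True):
        layer_table = intensity.per_layer_intensity(
            vol, stack, subtract_background=config["intensity"]["subtract_background"]
        )
        tables["intensity_layers"] = layer_table
        if not layer_table.empty:
            tables["intensity_totals"] = intensity.aggregate(
                layer_table, mode=config["intensity"]["mode"]
            )
            intensity.export_group_tables(
                layer_table,
                assignment.labels if assignment else None,
                out_dir / "intensity",
                mode=config["intensity"]["mode"],
            )

    if stages.get("texture", True):
        tables["texture"] = texture.texture_table(vol, stack)

    if stages.get("evaluate", True) and gt_labels is not None:
        tables["evaluation"] = evaluate.sweep_thresholds(gt_labels, vol)

    for name, df in tables.items():
        df.to_csv(out_dir / f"{name}.csv", index=False)
    stackio.save_session(
        out_dir / "session.zip",
        vol,
        tables=tables,
        voxel_size=voxel,
        metadata={"seed": config["seed"]},
    )
    return {"n_bundles": len(vol.id_set), "tables": sorted(tables)}


def run_pipeline(config: dict, out_root: str | Path) -> dict:
    """Process every sample in the config; failures are logged, not fatal.

    Each sample entry either names files on disk (``stack``, ``frames`` or
    ``labels``, optionally ``gt_labels``) or requests a phantom
    (``phantom: {...}`` with :class:`~bundlekit3d.phantoms.PhantomConfig`
    fields), which is also the self-test path: the phantom's ground truth
    doubles as the evaluation reference.
    """
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in config.items():
        if isinstance(value, dict) and key in merged:
            merged[key].update(value)
        else:
            merged[key] = value
    out_root = Path(out_root)
    out_root.mkdir(parents=True, exist_ok=True)
    summary: dict = {"ok": [], "failed": {}}
    for sample in merged["samples"]:
        name = sample["name"]
        try:
            if "phantom" in sample:
                fields = {
                    f.name: sample["phantom"][f.name]
                    for f in dataclasses.fields(phantoms.PhantomConfig)
                    if f.name in sample["phantom"]
                }
                if "seed" not in fields:
                    fields["seed"] = merged["seed"]
                cfg = phantoms.PhantomConfig(**{
                    k: tuple(v) if isinstance(v, list) else v for k, v in fields.items()
                })
                stack, gt, _truth = phantoms.generate_stack(cfg)
                series = phantoms.degrade_to_frame_masks(
                    gt,
                    dropout_rate=sample.get("dropout_rate", 0.0),
                    split_rate=sample.get("split_rate", 0.0),
                    seed=merged["seed"],
                )
            else:
                stack = stackio.read_stack(sample["stack"], voxel_size=tuple(merged["voxel_size"]))
                src = stackio.read_label_volume(sample["labels"])
                series = phantoms.degrade_to_frame_masks(src, seed=merged["seed"])
                gt = (
                    stackio.read_label_volume(sample["gt_labels"])
                    if "gt_labels" in sample
                    else None
                )
            result = run_sample(stack, series, out_root / name, merged, gt_labels=gt)
            summary["ok"].append(name)
            log.info("sample %s: %s", name, result)
        except Exception as exc:  # noqa: BLE001 — per-sample isolation is the contract
            log.error("sample %s failed: %s", name, exc)
            summary["failed"][name] = f"{type(exc).__name__}: {exc}"
            (out_root / f"{name}.failure.log").write_text(traceback.format_exc())
    (out_root / "batch_summary.json").write_text(json.dumps(summary, indent=2))
    return summary
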