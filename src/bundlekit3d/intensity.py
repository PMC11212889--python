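"""Depth-aware per-bundle fluorescence quantification.

Superimposes instance labels on a fluorescence channel and aggregates the
per-plane masked intensity sums S_i(z) into a per-bundle total under one of
three depth-handling modes (bundle depths d_i differ because segmentation
depth varies with signal strength):

1. ``all_layers``   — T1 = sum of S_i(z) over every occupied layer;
2. ``common_depth`` — sum of the first n occupied layers from the bundle's
   shallowest plane, n = min_i d_i over the comparison set, so every bundle
   contributes the same number of layers;
3. ``pad_to_max``   — T1 plus (n_max − d_i) copies of the bundle's weakest
   layer value, n_max = max_i d_i, so every bundle counts n_max values.

For non-negative intensities mode 2 ≤ mode 1 ≤ mode 3, with equality when
all depths match.  Optional background subtraction removes, per plane, the
mean intensity outside every mask times the bundle's voxel count in that
plane (clamped at zero).  Totals are compared after max normalization.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .stackio import LabelVolume, ZStack

__all__ = [
    "per_layer_intensity",
    "aggregate",
    "normalize_max",
    "export_group_tables",
    "MODES",
]

MODES = {1: "all_layers", 2: "common_depth", 3: "pad_to_max"}


def per_layer_intensity(
    labels: LabelVolume,
    fluor: ZStack,
    channel: int = 0,
    subtract_background: bool = False,
) -> pd.DataFrame:
    """Per-(bundle, z-plane) masked intensity sums.

    Returns a long table with columns ``id, z, sum, voxels``; a bundle's
    depth d_i is its number of rows.  Background, when subtracted, is the
    per-plane mean over voxels outside all masks.
    """
    grid = fluor.channel(channel)
    if grid.shape != labels.shape:
        raise ValueError(f"stack shape {grid.shape} != labels shape {labels.shape}")
    rows = []
    for z in range(labels.shape[0]):
        plane_labels = labels.labels[z]
        plane = grid[z].astype(float)
        outside = plane_labels == 0
        bg_mean = float(plane[outside].mean()) if outside.any() else 0.0
        for bundle_id in np.unique(plane_labels):
            if bundle_id == 0:
                continue
            mask = plane_labels == bundle_id
            n = int(mask.sum())
            total = float(plane[mask].sum())
            if subtract_background:
                total = max(total - bg_mean * n, 0.0)
            rows.append({"id": int(bundle_id), "z": z, "sum": total, "voxels": n})
    return pd.DataFrame.from_records(rows, columns=["id", "z", "sum", "voxels"])


def aggregate(
    table: pd.DataFrame,
    mode: int = 1,
    comparison_set: Iterable[int] | None = None,
    top_layers: str = "shallowest",
) -> pd.DataFrame:
    """Per-bundle totals under one depth-handling mode.

    ``comparison_set`` restricts which bundles define n / n_max (and are
    reported); default is every bundle in the table.  ``top_layers`` selects
    which n layers mode 2 keeps: ``shallowest`` (tip-side, the default) or
    ``brightest``.  Returns columns ``id, depth, total, mean``; the mean
    divides the all-layers total by the bundle's voxel count.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {sorted(MODES)}, got {mode}")
    if top_layers not in ("shallowest", "brightest"):
        raise ValueError(f"top_layers must be 'shallowest' or 'brightest', got {top_layers!r}")
    if table.empty:
        raise ValueError("empty intensity table")
    ids = sorted(comparison_set) if comparison_set is not None else sorted(table["id"].unique())
    sub = table[table["id"].isin(ids)]
    missing = set(ids) - set(sub["id"].unique())
    if missing:
        raise ValueError(f"bundles absent from intensity table: {sorted(missing)}")

    depths = sub.groupby("id")["z"].size()
    n_common = int(depths.min())
    n_max = int(depths.max())
    rows = []
    for bundle_id in ids:
        b = sub[sub["id"] == bundle_id].sort_values("z")
        sums = b["sum"].to_numpy(dtype=float)
        t1 = float(sums.sum())
        if mode == 1:
            total = t1
        elif mode == 2:
            if top_layers == "brightest":
                total = float(np.sort(sums)[::-1][:n_common].sum())
            else:
                total = float(sums[:n_common].sum())
        else:
            total = t1 + (n_max - len(sums)) * float(sums.min())
        rows.append(
            {
                "id": bundle_id,
                "depth": len(sums),
                "total": total,
                "mean": t1 / float(b["voxels"].sum()),
            }
        )
    return pd.DataFrame.from_records(rows)


def normalize_max(values: np.ndarray | pd.Series) -> np.ndarray:
    """Max normalization: v / max(v); the group maximum maps to 1."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot normalize an empty group")
    m = arr.max()
    if m <= 0:
        raise ValueError("group maximum must be positive for max normalization")
    return arr / m


def export_group_tables(
    table: pd.DataFrame,
    row_assignment: Mapping[int, str] | None,
    out_dir: str | Path,
    mode: int = 1,
    make_plots: bool = True,
) -> list[Path]:
    """Write per-cell-type intensity CSVs (and histograms).

    Groups are IHC, OHC (all three rows pooled), OHC1, OHC2, OHC3; each gets
    a mean-intensity and a total-intensity CSV — ten CSVs per stack, plus ten
    histogram images when plotting is enabled.  Missing row assignment
    degrades to a single ``all`` group with a warning column in no CSVs but a
    log message.
    """
    import logging

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    agg = aggregate(table, mode=mode)
    if agg.empty:
        logging.getLogger(__name__).warning("no bundles to export")
        return []
    if row_assignment is None:
        logging.getLogger(__name__).warning("no row assignment; exporting a single 'all' group")
        groups = {"all": agg}
    else:
        agg = agg.assign(row=[row_assignment.get(i, "unassigned") for i in agg["id"]])
        groups = {
            "IHC": agg[agg["row"] == "IHC"],
            "OHC": agg[agg["row"].isin(["OHC1", "OHC2", "OHC3"])],
            "OHC1": agg[agg["row"] == "OHC1"],
            "OHC2": agg[agg["row"] == "OHC2"],
            "OHC3": agg[agg["row"] == "OHC3"],
        }
    written: list[Path] = []
    for name, df in groups.items():
        for kind in ("mean", "total"):
            path = out_dir / f"intensity_{name}_{kind}.csv"
            df[["id", "depth", kind]].to_csv(path, index=False)
            written.append(path)
            if make_plots and not df.empty:
                import matplotlib

                matplotlib.use("Agg", force=False)
                import matplotlib.pyplot as plt

                fig, ax = plt.subplots(figsize=(4, 3))
                ax.hist(df[kind], bins=min(20, max(3, len(df))), color="#4477aa")
                ax.set_xlabel(f"{kind} intensity")
                ax.set_ylabel("bundles")
                ax.set_title(f"{name} ({len(df)} bundles)")
                fig.tight_layout()
                fig.savefig(out_dir / f"intensity_{name}_{kind}.png", dpi=100)
                plt.close(fig)
    return written
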