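"""Canonical data model and file I/O for z-stacks, label volumes and sessions.

All voxel grids are indexed ``(z, y, x)``, 0-based, with ``y`` increasing
downward (image convention).  Bounding boxes are half-open ``[lo, hi)``.
Physical voxel sizes are given as ``(sz, sy, sx)`` in micrometres per voxel.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

SESSION_FORMAT_VERSION = 1

__all__ = [
    "ZStack",
    "LabelVolume",
    "FrameMaskSeries",
    "read_stack",
    "write_stack",
    "read_label_volume",
    "write_label_volume",
    "save_session",
    "load_session",
    "SESSION_FORMAT_VERSION",
]


@dataclass
class ZStack:
    """An ordered stack of 2D intensity frames.

    Parameters
    ----------
    frames
        Voxel grid of shape ``(z, y, x)`` or ``(c, z, y, x)`` when multiple
        channels are present.  z index 0 is the first acquired plane (the
        "top" of the stack).
    voxel_size
        ``(sz, sy, sx)`` in µm per voxel; every component strictly positive.
    """

    frames: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise ValueError(
                f"frames must be (z, y, x) or (c, z, y, x); got shape {self.frames.shape}"
            )
        self.voxel_size = tuple(float(s) for s in self.voxel_size)  # type: ignore[assignment]
        if len(self.voxel_size) != 3 or any(s <= 0 for s in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 strictly positive values, got {self.voxel_size}")

    @property
    def n_channels(self) -> int:
        return 1 if self.frames.ndim == 3 else self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial shape ``(z, y, x)``."""
        return tuple(self.frames.shape[-3:])  # type: ignore[return-value]

    def channel(self, c: int = 0) -> np.ndarray:
        """Return the (z, y, x) grid of one channel."""
        if self.frames.ndim == 3:
            if c != 0:
                raise IndexError(f"single-channel stack has no channel {c}")
            return self.frames
        if not 0 <= c < self.frames.shape[0]:
            raise IndexError(f"channel {c} out of range for {self.frames.shape[0]} channels")
        return self.frames[c]


@dataclass
class LabelVolume:
    """Integer voxel grid; 0 is background, positive IDs are bundle instances."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3D (z, y, x); got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError(f"labels must be an integer grid, got dtype {self.labels.dtype}")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative (0 = background)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def id_set(self) -> list[int]:
        """Sorted positive IDs actually present in the grid."""
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i > 0]

    def support(self, bundle_id: int) -> np.ndarray:
        """Boolean (z, y, x) mask of one instance."""
        if bundle_id not in self.id_set:
            raise KeyError(f"bundle id {bundle_id} not present (have {self.id_set})")
        return self.labels == bundle_id


@dataclass
class FrameMaskSeries:
    """Per-frame 2D instance masks with frame-local IDs.

    Frame-local IDs carry no cross-frame meaning; :mod:`bundlekit3d.reconstruct`
    assigns the global IDs.
    """

    masks: list[np.ndarray]
    frame_index: list[int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.masks = [np.asarray(m) for m in self.masks]
        if not self.masks:
            raise ValueError("series must contain at least one frame")
        shape = self.masks[0].shape
        for m in self.masks:
            if m.ndim != 2 or m.shape != shape:
                raise ValueError("all frame masks must be 2D and share one shape")
            if not np.issubdtype(m.dtype, np.integer):
                raise ValueError("frame masks must be integer label images")
        if self.frame_index is None:
            self.frame_index = list(range(len(self.masks)))
        self.frame_index = [int(i) for i in self.frame_index]
        if len(self.frame_index) != len(self.masks):
            raise ValueError("frame_index length must match number of masks")
        if any(b <= a for a, b in zip(self.frame_index, self.frame_index[1:])):
            raise ValueError("frame indices must be strictly increasing")

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.masks[0].shape  # type: ignore[return-value]

    def __len__(self) -> int:
        return len(self.masks)


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

def read_stack(
    path: str | Path,
    voxel_size: tuple[float, float, float],
    channel_axis: int | None = None,
) -> ZStack:
    """Read a multi-page TIFF (or directory of per-plane TIFFs) as a ZStack.

    Voxel sizes are explicit configuration: TIFF metadata conventions vary
    between acquisition pipelines, so the caller always declares them.

    Parameters
    ----------
    path
        TIFF file, or a directory whose sorted ``*.tif``/``*.tiff`` members
        are the z-planes.
    voxel_size
        ``(sz, sy, sx)`` in µm per voxel.
    channel_axis
        Axis of the raw array holding channels, if any; moved to the leading
        axis of :attr:`ZStack.frames`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack: {path}")
    if path.is_dir():
        pages = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not pages:
            raise FileNotFoundError(f"directory {path} contains no TIFF planes")
        planes = [tifffile.imread(p) for p in pages]
        shapes = {p.shape for p in planes}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent plane shapes in {path}: {sorted(shapes)}")
        data = np.stack(planes)
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
    if channel_axis is not None:
        data = np.moveaxis(data, channel_axis, 0)
    return ZStack(frames=data, voxel_size=voxel_size)


def write_stack(stack: ZStack, path: str | Path) -> Path:
    """Write a ZStack to a multi-page TIFF, bit-exact on voxel values."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.frames, photometric="minisblack")
    return path


def _label_dtype(max_id: int, dtype: np.dtype | None) -> np.dtype:
    if dtype is not None:
        dtype = np.dtype(dtype)
        if max_id > np.iinfo(dtype).max:
            raise OverflowError(
                f"label id {max_id} does not fit pixel type {dtype} (max {np.iinfo(dtype).max})"
            )
        return dtype
    for cand in (np.uint8, np.uint16, np.uint32):
        if max_id <= np.iinfo(cand).max:
            return np.dtype(cand)
    return np.dtype(np.uint64)


def write_label_volume(vol: LabelVolume, path: str | Path, dtype: np.dtype | None = None) -> Path:
    """Write a label volume as a multi-page TIFF.

    The pixel type defaults to the smallest unsigned integer that holds the
    largest ID; an explicit ``dtype`` too small for the IDs raises
    :class:`OverflowError` rather than truncating.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    max_id = int(vol.labels.max()) if vol.labels.size else 0
    out_dtype = _label_dtype(max_id, dtype)
    tifffile.imwrite(path, vol.labels.astype(out_dtype), photometric="minisblack")
    return path


def read_label_volume(path: str | Path) -> LabelVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such label volume: {path}")
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return LabelVolume(labels=data.astype(np.int64))


# ---------------------------------------------------------------------------
# Session archive
# ---------------------------------------------------------------------------
# A session is a plain zip of a JSON manifest, the label volume as TIFF, and
# every analysis table as CSV -- portable and inspectable with standard tools,
# unlike a language-native pickle.

def save_session(
    path: str | Path,
    labels: LabelVolume,
    tables: Mapping[str, pd.DataFrame] | None = None,
    voxel_size: Sequence[float] | None = None,
    metadata: Mapping | None = None,
) -> Path:
    """Save an analysis state as a self-describing zip archive.

    ``tables`` maps a short name (e.g. ``"heights"``) to the DataFrame that a
    pipeline stage produced.  The round trip ``load_session(save_session(...))``
    reproduces the label volume and every table bit-exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tables = dict(tables or {})
    manifest = {
        "format_version": SESSION_FORMAT_VERSION,
        "voxel_size": list(voxel_size) if voxel_size is not None else None,
        "tables": sorted(tables),
        "metadata": dict(metadata or {}),
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=2))
        buf = io.BytesIO()
        max_id = int(labels.labels.max()) if labels.labels.size else 0
        tifffile.imwrite(buf, labels.labels.astype(_label_dtype(max_id, None)), photometric="minisblack")
        zf.writestr("labels.tif", buf.getvalue())
        for name, df in tables.items():
            zf.writestr(f"tables/{name}.csv", df.to_csv(index=False))
    return path


def load_session(path: str | Path) -> dict:
    """Load a session archive; returns manifest, label volume and tables."""
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        names = set(zf.namelist())
        if "manifest.json" not in names:
            raise ValueError(f"{path} is not a session archive: missing manifest.json")
        manifest = json.loads(zf.read("manifest.json"))
        version = manifest.get("format_version")
        if version != SESSION_FORMAT_VERSION:
            raise ValueError(
                f"session format version {version} is not supported "
                f"(this build reads version {SESSION_FORMAT_VERSION})"
            )
        missing = [m for m in ["labels.tif"] if m not in names]
        missing += [
            f"tables/{t}.csv" for t in manifest.get("tables", []) if f"tables/{t}.csv" not in names
        ]
        if missing:
            raise ValueError(f"session archive {path} is missing members: {missing}")
        data = tifffile.imread(io.BytesIO(zf.read("labels.tif")))
        if data.ndim == 2:
            data = data[None]
        tables = {
            t: pd.read_csv(io.BytesIO(zf.read(f"tables/{t}.csv")))
            for t in manifest.get("tables", [])
        }
    return {
        "manifest": manifest,
        "labels": LabelVolume(labels=data.astype(np.int64)),
        "tables": tables,
    }
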