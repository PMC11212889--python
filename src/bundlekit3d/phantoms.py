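"""Seeded synthetic z-stacks of V-shaped hair-cell bundles with ground truth.

The generator emulates an en-face confocal stack of one inner-hair-cell row
and three outer-hair-cell rows: each bundle is a V of two wings meeting at a
peak, extruded over a contiguous z-range, painted at a fixed amplitude over a
noisy background.  Default physical scale mirrors high-NA Airyscan imaging
(~0.043 µm xy, 0.110 µm z) so bundle heights land in the 1–5 µm range typical
of neonatal mouse cochlea.

Everything is deterministic for a fixed seed, and the returned
:class:`PhantomTruth` carries per-bundle landmarks, heights, angles, depths
and per-layer occupancies so every downstream stage has an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .stackio import FrameMaskSeries, LabelVolume, ZStack

ROW_LABELS = ("IHC", "OHC1", "OHC2", "OHC3")

__all__ = [
    "BundleSpec",
    "PhantomConfig",
    "PhantomTruth",
    "generate_stack",
    "degrade_to_frame_masks",
    "generate_zone_scores",
    "ROW_LABELS",
]


@dataclass
class BundleSpec:
    """Geometry of one V-shaped bundle, pre-rotation, in voxel units.

    The peak sits at ``(peak_y, peak_x)``; the two wings leave it downward
    (+y) at ``wing_half_angle_deg`` either side of vertical, with length
    ``wing_length_px`` and stroke thickness ``stroke_px``.  The bundle spans
    z-planes ``[z_start, z_start + depth)``, optionally drifting laterally by
    ``drift_yx_per_layer`` per plane.
    """

    peak_y: float
    peak_x: float
    wing_half_angle_deg: float = 40.0
    wing_length_px: float = 60.0
    stroke_px: float = 5.0
    z_start: int = 3
    depth: int = 24
    drift_yx_per_layer: tuple[float, float] = (0.0, 0.0)
    amplitude: float = 200.0
    row: str = "IHC"


@dataclass
class PhantomConfig:
    """Study conditions for one synthetic stack.

    ``row_y`` lists the peak y-position of each row ordered (IHC, OHC1,
    OHC2, OHC3); the IHC row is bottom-most (largest y), matching the
    post-alignment layout of real stacks.
    """

    shape: tuple[int, int, int] = (30, 384, 384)
    voxel_size: tuple[float, float, float] = (0.110, 0.043, 0.043)
    row_y: tuple[float, ...] = (300.0, 225.0, 150.0, 75.0)
    bundles_per_row: int = 4
    x_margin: float = 60.0
    wing_half_angle_deg: float = 40.0
    wing_length_px: float = 60.0
    stroke_px: float = 5.0
    z_start: int = 3
    depth: int = 24
    depth_jitter: int = 0          # uniform per-bundle jitter in layers
    position_jitter: float = 2.0   # uniform per-bundle peak jitter in px
    drift_yx_per_layer: tuple[float, float] = (0.0, 0.0)
    amplitude: float = 200.0
    background: float = 20.0
    noise_sd: float = 10.0
    rotation_deg: float = 0.0
    seed: int = 0
    bundles: Sequence[BundleSpec] | None = None

    def bundle_specs(self, rng: np.random.Generator) -> list[BundleSpec]:
        """Explicit bundles if given, else a jittered row/column grid."""
        if self.bundles is not None:
            return list(self.bundles)
        specs = []
        n = self.bundles_per_row
        xs = np.linspace(self.x_margin, self.shape[2] - 1 - self.x_margin, n)
        for row_i, ry in enumerate(self.row_y):
            label = ROW_LABELS[row_i % len(ROW_LABELS)]
            for x in xs:
                jy, jx = rng.uniform(-self.position_jitter, self.position_jitter, 2)
                depth = self.depth + int(rng.integers(-self.depth_jitter, self.depth_jitter + 1))
                specs.append(
                    BundleSpec(
                        peak_y=ry + jy,
                        peak_x=float(x) + jx,
                        wing_half_angle_deg=self.wing_half_angle_deg,
                        wing_length_px=self.wing_length_px,
                        stroke_px=self.stroke_px,
                        z_start=self.z_start,
                        depth=max(1, depth),
                        drift_yx_per_layer=self.drift_yx_per_layer,
                        amplitude=self.amplitude,
                        row=label,
                    )
                )
        return specs


@dataclass
class PhantomTruth:
    """Ground truth for one generated stack.

    ``table`` has one row per bundle: id, row, tip/base voxel coordinates,
    physical height (µm), baseline/axis angles (deg), depth (layers) and
    painted voxel count.  ``layers`` has one row per (id, z-plane) with the
    painted voxel count in that plane.
    """

    table: pd.DataFrame
    layers: pd.DataFrame
    labels: LabelVolume


def _wing_segments(
    spec: BundleSpec,
    layer: int,
    rotation_deg: float = 0.0,
    center: tuple[float, float] | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Wing endpoints for one z-layer, with the optional global stack
    rotation applied to the geometry itself (exact at any angle — the
    rasterization never resamples a rotated grid)."""
    a = np.deg2rad(spec.wing_half_angle_deg)
    dy, dx = spec.drift_yx_per_layer
    p = np.array([spec.peak_y + dy * layer, spec.peak_x + dx * layer])
    down = spec.wing_length_px * np.cos(a)
    out = spec.wing_length_px * np.sin(a)
    left = p + np.array([down, -out])
    right = p + np.array([down, out])
    pts = [p, left, right]
    if rotation_deg != 0.0 and center is not None:
        # same content convention as scipy.ndimage.rotate(angle, axes=(y, x)):
        # positive angle turns content clockwise on screen
        r = np.deg2rad(rotation_deg)
        R = np.array([[np.cos(r), -np.sin(r)], [np.sin(r), np.cos(r)]])
        c = np.asarray(center)
        pts = [c + R @ (q - c) for q in pts]
    p, left, right = pts
    return [(p, left), (p, right)]


def _paint_segment(mask: np.ndarray, p0: np.ndarray, p1: np.ndarray, half_width: float) -> None:
    """Set pixels whose centre lies within half_width of the segment.

    Exact point-to-segment distance thresholding: an isotropic stroke
    independent of wing angle, which keeps the morphometry oracles stable.
    """
    ylo = int(np.floor(min(p0[0], p1[0]) - half_width - 1))
    yhi = int(np.ceil(max(p0[0], p1[0]) + half_width + 1))
    xlo = int(np.floor(min(p0[1], p1[1]) - half_width - 1))
    xhi = int(np.ceil(max(p0[1], p1[1]) + half_width + 1))
    ylo, xlo = max(ylo, 0), max(xlo, 0)
    yhi, xhi = min(yhi, mask.shape[0] - 1), min(xhi, mask.shape[1] - 1)
    if yhi < ylo or xhi < xlo:
        return
    yy, xx = np.mgrid[ylo : yhi + 1, xlo : xhi + 1]
    d = np.stack([yy - p0[0], xx - p0[1]], axis=-1).astype(float)
    seg = p1 - p0
    seg_len2 = float(seg @ seg)
    t = np.clip((d @ seg) / seg_len2, 0.0, 1.0) if seg_len2 > 0 else np.zeros_like(yy, float)
    closest = t[..., None] * seg
    dist = np.sqrt(((d - closest) ** 2).sum(axis=-1))
    mask[ylo : yhi + 1, xlo : xhi + 1] |= dist <= half_width


def _bundle_plane_mask(
    spec: BundleSpec,
    layer: int,
    frame_shape: tuple[int, int],
    rotation_deg: float = 0.0,
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    mask = np.zeros(frame_shape, dtype=bool)
    for p0, p1 in _wing_segments(spec, layer, rotation_deg, center):
        _paint_segment(mask, p0, p1, spec.stroke_px / 2.0)
    return mask


def _check_bounds(
    spec: BundleSpec,
    bundle_id: int,
    shape: tuple[int, int, int],
    rotation_deg: float = 0.0,
    center: tuple[float, float] | None = None,
) -> list[str]:
    problems = []
    z_end = spec.z_start + spec.depth - 1
    if spec.z_start < 0 or z_end >= shape[0]:
        problems.append(f"id {bundle_id}: z-range [{spec.z_start}, {z_end}] outside 0..{shape[0] - 1}")
    for layer in (0, spec.depth - 1):
        for p0, p1 in _wing_segments(spec, layer, rotation_deg, center):
            for pt in (p0, p1):
                r = spec.stroke_px / 2.0
                if not (r <= pt[0] <= shape[1] - 1 - r and r <= pt[1] <= shape[2] - 1 - r):
                    problems.append(
                        f"id {bundle_id}: point (y={pt[0]:.1f}, x={pt[1]:.1f}) exceeds frame bounds"
                    )
    return problems


def _truth_landmarks(labels: np.ndarray, bundle_id: int) -> dict:
    """Tip/base landmarks computed directly on the ground-truth grid.

    Independent of :mod:`bundlekit3d.morphometry`: same documented landmark
    definitions (topmost projection pixel; downward trace from the projection
    centroid), separately coded so the two routes cross-check each other.
    """
    occ = labels == bundle_id
    proj = occ.any(axis=0)
    ys, xs = np.nonzero(proj)
    order = np.lexsort((xs, ys))
    ty, tx = int(ys[order[0]]), int(xs[order[0]])
    tz = int(np.nonzero(occ[:, ty, tx])[0].min())
    cy = int(round(ys.mean()))
    cx = int(round(xs.mean()))
    if not proj[cy, cx]:
        row_xs = np.nonzero(proj[cy, :])[0]
        if row_xs.size:
            cx = int(row_xs[np.abs(row_xs - cx).argmin()])
        else:
            flat = np.argmin((ys - cy) ** 2 + (xs - cx) ** 2)
            cy, cx = int(ys[flat]), int(xs[flat])
    y = cy
    while y + 1 < proj.shape[0] and proj[y + 1, cx]:
        y += 1
    bz = int(np.nonzero(occ.any(axis=(1, 2)))[0].max())
    return {"tip": (tz, ty, tx), "base": (bz, y, cx)}


def generate_stack(config: PhantomConfig) -> tuple[ZStack, LabelVolume, PhantomTruth]:
    """Rasterize a phantom stack, its label volume and full ground truth.

    Later bundles never overwrite earlier ones (overlaps keep the lower ID);
    the default grid is non-overlapping.  The optional global rotation is
    applied last, to the wing geometry about the frame centre, so every angle
    rasterizes exactly (no grid resampling); background and Gaussian noise
    are then added, and the label volume stays noise-free.
    """
    rng = np.random.default_rng(config.seed)
    specs = config.bundle_specs(rng)
    Z, Y, X = config.shape
    labels = np.zeros((Z, Y, X), dtype=np.int32)
    signal = np.zeros((Z, Y, X), dtype=float)
    center = ((Y - 1) / 2.0, (X - 1) / 2.0)
    rot = config.rotation_deg

    problems: list[str] = []
    for i, spec in enumerate(specs, start=1):
        problems += _check_bounds(spec, i, config.shape, rot, center)
    if problems:
        raise ValueError("bundles exceed stack bounds:\n  " + "\n  ".join(problems))

    for i, spec in enumerate(specs, start=1):
        for layer in range(spec.depth):
            z = spec.z_start + layer
            mask = _bundle_plane_mask(spec, layer, (Y, X), rot, center)
            free = mask & (labels[z] == 0)
            labels[z][free] = i
            signal[z][free] = spec.amplitude

    frames = signal + config.background + rng.normal(0.0, config.noise_sd, size=signal.shape)
    frames = np.clip(frames, 0.0, None)

    sz, sy, sx = config.voxel_size
    records = []
    layer_records = []
    for i, spec in enumerate(specs, start=1):
        lm = _truth_landmarks(labels, i)
        (tz, ty, tx), (bz, by, bx) = lm["tip"], lm["base"]
        height = float(
            np.sqrt((sz * (bz - tz)) ** 2 + (sy * (by - ty)) ** 2 + (sx * (bx - tx)) ** 2)
        )
        occ = labels == i
        zs = np.nonzero(occ.any(axis=(1, 2)))[0]
        for z in zs:
            layer_records.append({"id": i, "z": int(z), "voxels": int(occ[z].sum())})
        records.append(
            {
                "id": i,
                "row": spec.row,
                "tip_z": tz, "tip_y": ty, "tip_x": tx,
                "base_z": bz, "base_y": by, "base_x": bx,
                "height_um": height,
                # positive rotation_deg turns content clockwise on screen
                # (scipy axes=(y, x)), so a horizontal baseline reads -angle
                "baseline_angle_deg": (-config.rotation_deg) % 180.0,
                "axis_angle_deg": (90.0 - config.rotation_deg) % 180.0,
                "depth": int(len(zs)),
                "voxels": int(occ.sum()),
                "peak_y": spec.peak_y,
                "peak_x": spec.peak_x,
            }
        )
    truth = PhantomTruth(
        table=pd.DataFrame.from_records(records),
        layers=pd.DataFrame.from_records(layer_records),
        labels=LabelVolume(labels=labels.astype(np.int64)),
    )
    stack = ZStack(frames=frames, voxel_size=config.voxel_size)
    return stack, truth.labels, truth


def default_config(**overrides) -> PhantomConfig:
    """The standard study conditions with selected fields overridden."""
    return replace(PhantomConfig(), **overrides)


# ---------------------------------------------------------------------------
# Degradation to per-frame 2D masks
# ---------------------------------------------------------------------------

def _split_component(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a 2D support in two across its minor axis (i.e. cutting the
    major axis at its midpoint)."""
    ys, xs = np.nonzero(mask)
    pts = np.stack([ys, xs], axis=1).astype(float)
    centred = pts - pts.mean(axis=0)
    if len(pts) < 2:
        return mask.copy(), np.zeros_like(mask)
    cov = np.cov(centred.T)
    vals, vecs = np.linalg.eigh(np.atleast_2d(cov))
    major = vecs[:, np.argmax(vals)]
    proj = centred @ major
    a = np.zeros_like(mask)
    b = np.zeros_like(mask)
    half = proj >= np.median(proj)
    a[ys[half], xs[half]] = True
    b[ys[~half], xs[~half]] = True
    if not b.any():  # degenerate: all projections equal
        return mask.copy(), np.zeros_like(mask)
    return a, b


def degrade_to_frame_masks(
    vol: LabelVolume,
    dropout_rate: float = 0.0,
    split_rate: float = 0.0,
    seed: int = 0,
) -> FrameMaskSeries:
    """Turn a label volume into per-frame masks a 2D segmenter might emit.

    Per plane, each instance's support becomes one frame-local object (its
    connected components, so a bundle split by occlusion yields several);
    with probability ``dropout_rate`` an instance's mask is deleted from a
    frame, and with probability ``split_rate`` it is cut in two across its
    minor axis.  Frame-local IDs are randomly permuted per frame.
    """
    if not 0.0 <= dropout_rate <= 1.0 or not 0.0 <= split_rate <= 1.0:
        raise ValueError("dropout_rate and split_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    masks = []
    for z in range(vol.shape[0]):
        plane = vol.labels[z]
        objects: list[np.ndarray] = []
        for bundle_id in np.unique(plane):
            if bundle_id == 0:
                continue
            support = plane == bundle_id
            if rng.random() < dropout_rate:
                continue
            comp, n = ndimage.label(support)
            parts = [comp == k for k in range(1, n + 1)]
            if rng.random() < split_rate:
                parts = [piece for p in parts for piece in _split_component(p) if piece.any()]
            objects.extend(parts)
        out = np.zeros(plane.shape, dtype=np.int32)
        local_ids = rng.permutation(len(objects)) + 1
        for lid, obj in zip(local_ids, objects):
            out[obj] = lid
        masks.append(out)
    return FrameMaskSeries(masks=masks)


# ---------------------------------------------------------------------------
# Synthetic per-frame zone classifier scores
# ---------------------------------------------------------------------------

def generate_zone_scores(
    n_frames: int,
    boundaries: tuple[int, int],
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth zone labels and noisy 3-class score rows for a stack.

    ``boundaries = (pcz_end, ccz_end)``: frames ``[0, pcz_end)`` are PCZ (0),
    ``[pcz_end, ccz_end)`` are CCZ (1) and the rest NSZ (2).  Scores are the
    one-hot truth plus uniform noise, renormalized to sum to one per frame;
    with ``noise`` below 1 the argmax still equals the truth.
    """
    pcz_end, ccz_end = boundaries
    if not 0 <= pcz_end <= ccz_end <= n_frames:
        raise ValueError(f"invalid zone boundaries {boundaries} for {n_frames} frames")
    truth = np.full(n_frames, 2, dtype=int)
    truth[:ccz_end] = 1
    truth[:pcz_end] = 0
    rng = np.random.default_rng(seed)
    scores = np.eye(3)[truth] + noise * rng.random((n_frames, 3))
    scores /= scores.sum(axis=1, keepdims=True)
    return truth, scores
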