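"""Per-bundle morphometry: region measurements, tip-to-base height, and
V-bundle orientation.

Height is the 3D Euclidean distance between two landmarks of each instance:
the *tip* (topmost pixel of the z-projection, i.e. the bundle peak) and the
*base* (found by tracing straight down from the projection centroid to the
last occupied pixel), each given its z-coordinate from the 3D support and
scaled per-axis by the physical voxel size

    height = sqrt((sx*dx)^2 + (sy*dy)^2 + (sz*dz)^2)   [µm]

Because the trace follows the bundle through the z-stack rather than a
projected extent, the measure is insensitive to in-plane rotation.

Orientation treats the z-projection as a V: a peak and one anchor point per
side of the centroid, connected into a baseline (left-right), an axis
(baseline midpoint to peak) and an apex opening angle, all from ``atan2`` in
image coordinates (y down) and mapped to [0, 180).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

from .stackio import LabelVolume

__all__ = [
    "BinaryProjection",
    "HeightMeasurement",
    "OrientationResult",
    "project_z",
    "tip_base_points",
    "bundle_height",
    "measure_heights",
    "region_measurements",
    "orientation_height_only",
    "orientation_height_distance",
    "angles_from_points",
    "measure_orientations",
]


@dataclass
class BinaryProjection:
    """2D (y, x) support of a bundle: nonzero iff occupied in some z-plane."""

    grid: np.ndarray
    bundle_id: int


@dataclass
class HeightMeasurement:
    bundle_id: int
    tip: tuple[int, int, int]   # (x1, y1, z1)
    base: tuple[int, int, int]  # (x2, y2, z2)
    height_um: float | None = None
    snapped: bool = False       # base column was snapped to nearest support


@dataclass
class OrientationResult:
    bundle_id: int
    left: tuple[float, float]   # (x, y)
    right: tuple[float, float]
    peak: tuple[float, float]
    baseline_angle_deg: float
    axis_angle_deg: float
    apex_angle_deg: float
    method: str
    degenerate: bool = False


def project_z(vol: LabelVolume, bundle_id: int) -> BinaryProjection:
    """Binary z-projection of one instance (sum along z clamped to 0/1)."""
    support = vol.support(bundle_id)
    return BinaryProjection(grid=support.any(axis=0), bundle_id=bundle_id)


def tip_base_points(vol: LabelVolume, bundle_id: int) -> HeightMeasurement:
    """Locate the tip and base landmarks of one bundle.

    Tip: the projection pixel with minimal y (tie: minimal x); its z is the
    shallowest plane where that (y, x) voxel belongs to the bundle.  Base:
    starting from the projection centroid (x snapped to the nearest support
    column in the centroid row if the centroid itself is off-support), walk
    straight down (+y) at fixed x until the first empty pixel and step back
    one; its z is the deepest plane occupied by the whole component.
    """
    support = vol.support(bundle_id)
    proj = support.any(axis=0)
    ys, xs = np.nonzero(proj)

    tip_row = ys.min()
    tip_col = xs[ys == tip_row].min()
    z1 = int(np.nonzero(support[:, tip_row, tip_col])[0].min())

    cy = int(round(float(ys.mean())))
    cx = int(round(float(xs.mean())))
    cy = int(np.clip(cy, 0, proj.shape[0] - 1))
    cx = int(np.clip(cx, 0, proj.shape[1] - 1))
    snapped = False
    if not proj[cy, cx]:
        snapped = True
        row_support = np.nonzero(proj[cy, :])[0]
        if row_support.size:
            cx = int(row_support[np.argmin(np.abs(row_support - cx))])
        else:
            # centroid row entirely empty (e.g. split support): nearest pixel
            nearest = np.argmin((ys - cy) ** 2 + (xs - cx) ** 2)
            cy, cx = int(ys[nearest]), int(xs[nearest])
    by = cy
    while by + 1 < proj.shape[0] and proj[by + 1, cx]:
        by += 1
    z2 = int(np.nonzero(support.any(axis=(1, 2)))[0].max())

    return HeightMeasurement(
        bundle_id=bundle_id,
        tip=(int(tip_col), int(tip_row), z1),
        base=(int(cx), int(by), z2),
        snapped=snapped,
    )


def bundle_height(m: HeightMeasurement, voxel_size: tuple[float, float, float]) -> float:
    """Physical tip-to-base distance, per-axis scaled."""
    sz, sy, sx = voxel_size
    if sz <= 0 or sy <= 0 or sx <= 0:
        raise ValueError(f"voxel_size must be positive, got {voxel_size}")
    dx = (m.base[0] - m.tip[0]) * sx
    dy = (m.base[1] - m.tip[1]) * sy
    dz = (m.base[2] - m.tip[2]) * sz
    return float(np.sqrt(dx * dx + dy * dy + dz * dz))


def measure_heights(vol: LabelVolume, voxel_size: tuple[float, float, float]) -> pd.DataFrame:
    """Height table for every instance: id, x1..z2 endpoints, height_um."""
    rows = []
    for bundle_id in vol.id_set:
        m = tip_base_points(vol, bundle_id)
        m.height_um = bundle_height(m, voxel_size)
        rows.append(
            {
                "id": bundle_id,
                "x1": m.tip[0], "y1": m.tip[1], "z1": m.tip[2],
                "x2": m.base[0], "y2": m.base[1], "z2": m.base[2],
                "height_um": m.height_um,
                "snapped": m.snapped,
            }
        )
    return pd.DataFrame.from_records(
        rows, columns=["id", "x1", "y1", "z1", "x2", "y2", "z2", "height_um", "snapped"]
    )


# ---------------------------------------------------------------------------
# 15-metric measurement table
# ---------------------------------------------------------------------------

def _surface_area_voxels(support: np.ndarray, voxel_size: tuple[float, float, float]) -> float:
    """Physical area of exposed voxel faces."""
    sz, sy, sx = voxel_size
    face_area = {0: sy * sx, 1: sz * sx, 2: sz * sy}
    total = 0.0
    padded = np.pad(support, 1)
    for axis, area in face_area.items():
        diff = np.diff(padded.astype(np.int8), axis=axis)
        total += float(np.abs(diff).sum()) * area
    return total


def region_measurements(vol: LabelVolume, voxel_size: tuple[float, float, float]) -> pd.DataFrame:
    """Fifteen 2D/3D measurements per instance.

    3D: voxel count, physical volume, centroid (voxel and µm), surface area
    (exposed faces), bounding box (half-open), z-depth in layers.  2D (on the
    binary z-projection, xy pixels assumed square at sx): area, perimeter,
    eccentricity, major/minor axis lengths, equivalent diameter, solidity,
    extent, major-axis orientation in degrees.
    """
    sz, sy, sx = voxel_size
    rows = []
    for bundle_id in vol.id_set:
        support = vol.support(bundle_id)
        n_vox = int(support.sum())
        zs, ys, xs = np.nonzero(support)
        centroid = (float(zs.mean()), float(ys.mean()), float(xs.mean()))
        proj = support.any(axis=0).astype(np.uint8)
        props = measure.regionprops(proj)[0]
        if n_vox == 1:
            perimeter_um = 4.0 * sx
            eccentricity = 0.0
        else:
            perimeter_um = float(props.perimeter) * sx
            eccentricity = float(props.eccentricity)
        rows.append(
            {
                "id": bundle_id,
                "volume_voxels": n_vox,
                "volume_um3": n_vox * sz * sy * sx,
                "centroid_z": centroid[0], "centroid_y": centroid[1], "centroid_x": centroid[2],
                "centroid_z_um": centroid[0] * sz,
                "centroid_y_um": centroid[1] * sy,
                "centroid_x_um": centroid[2] * sx,
                "surface_area_um2": _surface_area_voxels(support, voxel_size),
                "bbox_z0": int(zs.min()), "bbox_z1": int(zs.max()) + 1,
                "bbox_y0": int(ys.min()), "bbox_y1": int(ys.max()) + 1,
                "bbox_x0": int(xs.min()), "bbox_x1": int(xs.max()) + 1,
                "depth_layers": int(np.unique(zs).size),
                "projection_area_px": int(props.area),
                "perimeter_um": perimeter_um,
                "eccentricity": eccentricity,
                "major_axis_px": float(props.axis_major_length),
                "minor_axis_px": float(props.axis_minor_length),
                "equivalent_diameter_px": float(props.equivalent_diameter_area),
                "solidity": float(props.solidity),
                "extent": float(props.extent),
                "projection_orientation_deg": float(np.rad2deg(props.orientation)),
            }
        )
    return pd.DataFrame.from_records(rows)


# ---------------------------------------------------------------------------
# Orientation
# ---------------------------------------------------------------------------

def _peak_pixel(proj: np.ndarray) -> tuple[float, float]:
    """Orientation peak: centre of the topmost pixel run, as (x, y).

    Averaging x over the minimal-y pixels keeps a perfectly symmetric V's
    axis at exactly 90°, which a corner-of-the-run pick would bias.
    """
    ys, xs = np.nonzero(proj)
    top = ys.min()
    return float(xs[ys == top].mean()), float(top)


def angles_from_points(
    left: tuple[float, float], right: tuple[float, float], peak: tuple[float, float]
) -> tuple[float, float, float]:
    """(baseline, axis, apex) angles in degrees from three (x, y) points.

    Image convention (y down).  Baseline: direction left→right; axis:
    baseline midpoint→peak; both mapped to [0, 180).  Apex: opening angle at
    the peak between the two anchor points.  Coincident left/right points
    raise ValueError (undefined baseline).
    """
    lx, ly = left
    rx, ry = right
    px, py = peak
    if lx == rx and ly == ry:
        raise ValueError("left and right points coincide; angles undefined")
    baseline = np.degrees(np.arctan2(ry - ly, rx - lx)) % 180.0
    mx, my = (lx + rx) / 2.0, (ly + ry) / 2.0
    axis = np.degrees(np.arctan2(py - my, px - mx)) % 180.0
    v1 = np.array([lx - px, ly - py], dtype=float)
    v2 = np.array([rx - px, ry - py], dtype=float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("peak coincides with an anchor point; apex angle undefined")
    apex = np.degrees(np.arccos(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)))
    return float(baseline), float(axis), float(apex)


def orientation_height_only(proj: BinaryProjection) -> OrientationResult:
    """Anchors = the lowest pixel on each side of the centroid column.

    Ties on lowest y resolve to the pixel farthest from the centroid column.
    Works for clean V shapes; a side with no pixels marks the result
    degenerate and falls back to the height-and-distance rule.
    """
    grid = proj.grid.astype(bool)
    ys, xs = np.nonzero(grid)
    if ys.size == 0:
        raise ValueError(f"projection of bundle {proj.bundle_id} is empty")
    cx = float(xs.mean())
    px, py = _peak_pixel(grid)

    sides = {"left": xs < cx, "right": xs > cx}
    anchors = {}
    for name, mask in sides.items():
        if not mask.any():
            fallback = orientation_height_distance(proj)
            fallback.degenerate = True
            return fallback
        sy, sx_ = ys[mask], xs[mask]
        low = sy.max()
        cand = sx_[sy == low]
        anchors[name] = (float(cand[np.argmax(np.abs(cand - cx))]), float(low))

    baseline, axis, apex = angles_from_points(anchors["left"], anchors["right"], (px, py))
    return OrientationResult(
        bundle_id=proj.bundle_id,
        left=anchors["left"], right=anchors["right"], peak=(float(px), float(py)),
        baseline_angle_deg=baseline, axis_angle_deg=axis, apex_angle_deg=apex,
        method="height_only",
    )


def orientation_height_distance(proj: BinaryProjection, tolerance_px: int = 2) -> OrientationResult:
    """Anchors = among near-lowest pixels per side (within ``tolerance_px``
    of the side's lowest y), the one farthest from the peak.

    Accommodates curved or asymmetric bundles whose lowest pixel is not the
    wing end.
    """
    grid = proj.grid.astype(bool)
    ys, xs = np.nonzero(grid)
    if ys.size == 0:
        raise ValueError(f"projection of bundle {proj.bundle_id} is empty")
    cx = float(xs.mean())
    px, py = _peak_pixel(grid)

    anchors = {}
    degenerate = False
    for name, mask in (("left", xs < cx), ("right", xs > cx)):
        if not mask.any():
            # single-column support: reuse the column itself on both sides
            mask = np.ones_like(xs, dtype=bool)
            degenerate = True
        sy, sx_ = ys[mask], xs[mask]
        band = sy >= sy.max() - tolerance_px
        by, bx = sy[band], sx_[band]
        dist = (bx - px) ** 2 + (by - py) ** 2
        order = np.lexsort((bx, -by, -dist))
        anchors[name] = (float(bx[order[0]]), float(by[order[0]]))

    if anchors["left"] == anchors["right"]:
        left = anchors["left"]
        return OrientationResult(
            bundle_id=proj.bundle_id, left=left, right=left, peak=(float(px), float(py)),
            baseline_angle_deg=float("nan"), axis_angle_deg=float("nan"),
            apex_angle_deg=float("nan"), method="height_distance", degenerate=True,
        )
    baseline, axis, apex = angles_from_points(anchors["left"], anchors["right"], (px, py))
    return OrientationResult(
        bundle_id=proj.bundle_id,
        left=anchors["left"], right=anchors["right"], peak=(float(px), float(py)),
        baseline_angle_deg=baseline, axis_angle_deg=axis, apex_angle_deg=apex,
        method="height_distance", degenerate=degenerate,
    )


def measure_orientations(
    vol: LabelVolume, method: str = "height_distance", tolerance_px: int = 2
) -> pd.DataFrame:
    """Orientation table for every instance; all three angles exported.

    The headline ``orientation_deg`` column is the axis angle (baseline
    midpoint to peak): an upright V reads 90°.
    """
    if method not in ("height_only", "height_distance"):
        raise ValueError(f"unknown orientation method {method!r}")
    rows = []
    for bundle_id in vol.id_set:
        proj = project_z(vol, bundle_id)
        if method == "height_only":
            res = orientation_height_only(proj)
        else:
            res = orientation_height_distance(proj, tolerance_px=tolerance_px)
        rows.append(
            {
                "id": bundle_id,
                "left_x": res.left[0], "left_y": res.left[1],
                "right_x": res.right[0], "right_y": res.right[1],
                "peak_x": res.peak[0], "peak_y": res.peak[1],
                "baseline_angle_deg": res.baseline_angle_deg,
                "orientation_deg": res.axis_angle_deg,
                "apex_angle_deg": res.apex_angle_deg,
                "method": res.method,
                "degenerate": res.degenerate,
            }
        )
    return pd.DataFrame.from_records(rows)
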