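"""GLCM and LBP texture features of per-bundle crops, with nonparametric
two-group comparison.

Bundle disorganization phenotypes (e.g. loss of tip-link cadherins) show up
as texture shifts in the segmented crops: more heterogeneous bundles raise
gray-level co-occurrence contrast and lower homogeneity, energy and
correlation, while local-binary-pattern histograms shift mass between
pattern bins.  Features here follow the standard definitions on a
symmetric, normalized co-occurrence matrix P:

    contrast    = Σ P(i,j) (i−j)²
    energy      = Σ P(i,j)²            (angular second moment)
    homogeneity = Σ P(i,j) / (1 + |i−j|)
    correlation = Σ P(i,j) (i−µ_i)(j−µ_j) / (σ_i σ_j)

averaged over the angle set.  LBP uses the uniform mapping with P=8
neighbours at radius 1, giving a 10-bin histogram (codes 0–8 plus the
non-uniform bin).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from skimage.feature import graycomatrix, local_binary_pattern

from .stackio import LabelVolume, ZStack

__all__ = [
    "glcm_features",
    "lbp_histogram",
    "group_compare",
    "extract_crops",
    "texture_table",
]

DEFAULT_ANGLES_DEG = (0.0, 45.0, 90.0, 135.0)
GLCM_FEATURES = ("contrast", "correlation", "energy", "homogeneity")


def _quantize(crop: np.ndarray, levels: int) -> np.ndarray:
    """Rescale a crop onto [0, levels) integer gray levels."""
    crop = np.asarray(crop, dtype=float)
    lo, hi = crop.min(), crop.max()
    if hi == lo:
        return np.zeros(crop.shape, dtype=np.uint16)
    q = np.floor((crop - lo) / (hi - lo) * levels).astype(np.uint16)
    return np.minimum(q, levels - 1)


def glcm_features(
    crop: np.ndarray,
    levels: int = 256,
    distances: tuple[int, ...] = (1,),
    angles_deg: tuple[float, ...] = DEFAULT_ANGLES_DEG,
) -> dict:
    """Contrast, correlation, energy and homogeneity of one crop.

    The co-occurrence matrix is symmetric and normalized, and features are
    averaged over all (distance, angle) pairs.  A constant crop has a single
    co-occurrence cell: contrast 0, energy 1, homogeneity 1, and correlation
    undefined (NaN, flagged) since both marginal variances vanish.
    """
    crop = np.asarray(crop)
    if crop.ndim != 2 or min(crop.shape) < 2:
        raise ValueError(f"crop must be at least 2×2, got shape {crop.shape}")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    q = _quantize(crop, levels)
    constant = crop.max() == crop.min()
    angles = [np.deg2rad(a) for a in angles_deg]
    P = graycomatrix(q, distances=distances, angles=angles, levels=levels, symmetric=True, normed=True)

    i = np.arange(levels)[:, None]
    j = np.arange(levels)[None, :]
    contrasts, energies, homogeneities, correlations = [], [], [], []
    for di in range(P.shape[2]):
        for ai in range(P.shape[3]):
            p = P[:, :, di, ai]
            contrasts.append(float((p * (i - j) ** 2).sum()))
            energies.append(float((p**2).sum()))
            homogeneities.append(float((p / (1.0 + np.abs(i - j))).sum()))
            mu_i = float((p.sum(axis=1) * i[:, 0]).sum())
            mu_j = float((p.sum(axis=0) * j[0, :]).sum())
            var_i = float((p.sum(axis=1) * (i[:, 0] - mu_i) ** 2).sum())
            var_j = float((p.sum(axis=0) * (j[0, :] - mu_j) ** 2).sum())
            if var_i <= 0 or var_j <= 0:
                correlations.append(np.nan)
            else:
                cov = float((p * (i - mu_i) * (j - mu_j)).sum())
                correlations.append(cov / np.sqrt(var_i * var_j))

    corr = np.asarray(correlations, dtype=float)
    return {
        "contrast": float(np.mean(contrasts)),
        "correlation": float(np.nanmean(corr)) if np.isfinite(corr).any() else float("nan"),
        "energy": float(np.mean(energies)),
        "homogeneity": float(np.mean(homogeneities)),
        "correlation_defined": bool(np.isfinite(corr).any()) and not constant,
    }


def lbp_histogram(crop: np.ndarray, P: int = 8, R: float = 1.0) -> np.ndarray:
    """Normalized 10-bin uniform-LBP histogram (codes 0..P plus non-uniform).

    Pixels within ``R`` of the crop border are excluded: their circular
    neighbourhoods would sample outside the crop and produce artifact codes.
    """
    crop = np.asarray(crop, dtype=float)
    margin = int(np.ceil(R))
    if crop.ndim != 2 or min(crop.shape) < 2 * margin + 1:
        raise ValueError(f"crop too small for LBP radius {R}: shape {crop.shape}")
    import warnings

    with warnings.catch_warnings():
        # float inputs are fine here: comparisons are >= against the centre,
        # and monotone-transform invariance is property-tested
        warnings.filterwarnings("ignore", message=".*floating-point images.*")
        codes = local_binary_pattern(crop, P, R, method="uniform")
    interior = codes[margin:-margin, margin:-margin]
    hist, _ = np.histogram(interior, bins=np.arange(P + 3) - 0.5)
    return hist / hist.sum()


def group_compare(features_a: pd.DataFrame, features_b: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Two-sided Mann–Whitney U per feature column, with group medians.

    The U statistic is the first group's; exact p-values for small tie-free
    samples, tie-corrected normal approximation otherwise.  An all-identical
    pooled sample yields p = 1 with a tie note.
    """
    if len(features_a) == 0 or len(features_b) == 0:
        raise ValueError("both groups must be non-empty")
    if columns is None:
        columns = [c for c in features_a.columns if np.issubdtype(features_a[c].dtype, np.number)]
    rows = []
    for col in columns:
        a = features_a[col].dropna().to_numpy(dtype=float)
        b = features_b[col].dropna().to_numpy(dtype=float)
        note = ""
        if a.size == 0 or b.size == 0:
            rows.append({"feature": col, "U": np.nan, "p": np.nan,
                         "median_a": np.nan, "median_b": np.nan, "note": "empty after NaN drop"})
            continue
        pooled = np.concatenate([a, b])
        if np.unique(pooled).size == 1:
            u, p = a.size * b.size / 2.0, 1.0
            note = "all pooled values identical"
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            u, p = float(res.statistic), float(res.pvalue)
        rows.append({
            "feature": col, "U": u, "p": p,
            "median_a": float(np.median(a)), "median_b": float(np.median(b)),
            "note": note,
        })
    return pd.DataFrame.from_records(rows)


# ---------------------------------------------------------------------------
# Crops from labeled stacks
# ---------------------------------------------------------------------------

def extract_crops(
    labels: LabelVolume,
    stack: ZStack,
    channel: int = 0,
    pad_px: int = 2,
) -> dict[int, np.ndarray]:
    """Per-bundle 2D crops for texture analysis.

    Each crop is the bundle's bounding box of the max-intensity projection,
    masked to the bundle's projected support; off-support pixels take the
    plane-background mean so crop statistics reflect the bundle, not its
    neighbours.
    """
    grid = stack.channel(channel)
    if grid.shape != labels.shape:
        raise ValueError(f"stack shape {grid.shape} != labels shape {labels.shape}")
    mip = grid.max(axis=0).astype(float)
    outside = labels.labels.max(axis=0) == 0
    background = float(mip[outside].mean()) if outside.any() else float(mip.mean())
    crops = {}
    for bundle_id in labels.id_set:
        proj = (labels.labels == bundle_id).any(axis=0)
        ys, xs = np.nonzero(proj)
        y0, y1 = max(ys.min() - pad_px, 0), min(ys.max() + pad_px + 1, proj.shape[0])
        x0, x1 = max(xs.min() - pad_px, 0), min(xs.max() + pad_px + 1, proj.shape[1])
        crop = np.full((y1 - y0, x1 - x0), background)
        window = proj[y0:y1, x0:x1]
        crop[window] = mip[y0:y1, x0:x1][window]
        crops[bundle_id] = crop
    return crops


def texture_table(
    labels: LabelVolume,
    stack: ZStack,
    channel: int = 0,
    levels: int = 256,
) -> pd.DataFrame:
    """GLCM + LBP features for every bundle crop in a stack."""
    rows = []
    for bundle_id, crop in extract_crops(labels, stack, channel=channel).items():
        feats = glcm_features(crop, levels=levels)
        hist = lbp_histogram(crop)
        row = {"id": bundle_id, **{k: feats[k] for k in GLCM_FEATURES}}
        row.update({f"lbp_{i}": float(v) for i, v in enumerate(hist)})
        rows.append(row)
    return pd.DataFrame.from_records(rows)
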