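"""Frame-level inference rules around pluggable per-frame classifiers.

A z-stack traverses three focus zones: the pre-cellular zone (PCZ, class 0)
before tissue appears, the cellular clarity zone (CCZ, class 1) with
well-resolved bundles, and the noise saturation zone (NSZ, class 2) where
quality degrades.  Only CCZ frames are analyzed downstream.  This module
implements the deterministic logic layered on any per-frame classifier's
outputs: zone-range selection, the "switches" prediction-stability count,
confusion-matrix summary metrics, rotation-angle aggregation over 72 5°
classes with padding-free cropping, and the 13-frame tonotopic majority
vote.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "ZoneLabels",
    "confusion_metrics",
    "count_switches",
    "ccz_range",
    "zone_labels_from_scores",
    "aggregate_rotation",
    "largest_rotated_rect",
    "rotate_and_crop_max_rect",
    "tonotopic_vote",
    "TONOTOPIC_CLASSES",
]

TONOTOPIC_CLASSES = ("BASE", "MIDDLE", "APEX")


@dataclass
class ZoneLabels:
    labels: np.ndarray                 # per-frame class in {0, 1, 2}
    ccz: tuple[int, int] | None        # inclusive (first, last) or None
    switches: int


# ---------------------------------------------------------------------------
# Confusion-matrix metrics
# ---------------------------------------------------------------------------

def confusion_metrics(cm: np.ndarray) -> dict:
    """Macro-averaged one-vs-rest metrics from a k×k confusion matrix.

    Rows are true classes, columns predictions.  Precision, recall,
    specificity and F1 are per-class one-vs-rest then averaged over classes;
    a zero denominator leaves that class out as undefined (NaN) rather than
    counting it as 0.  Accuracy is the diagonal fraction, so
    accuracy + error_rate = 1 for single-label classification.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError(f"confusion matrix must be square, got {cm.shape}")
    if (cm < 0).any():
        raise ValueError("confusion matrix counts must be non-negative")
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")

    k = cm.shape[0]
    per_class = {}
    for i in range(k):
        tp = cm[i, i]
        fn = cm[i, :].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        per_class[i] = {
            "tp": int(tp), "fp": int(fp), "fn": int(fn), "tn": int(tn),
            "precision": tp / (tp + fp) if tp + fp else np.nan,
            "recall": tp / (tp + fn) if tp + fn else np.nan,
            "specificity": tn / (tn + fp) if tn + fp else np.nan,
        }
        p, r = per_class[i]["precision"], per_class[i]["recall"]
        per_class[i]["f1"] = (
            2 * p * r / (p + r) if np.isfinite(p) and np.isfinite(r) and (p + r) > 0 else np.nan
        )

    def macro(key: str) -> float:
        vals = [per_class[i][key] for i in range(k)]
        finite = [v for v in vals if np.isfinite(v)]
        return float(np.mean(finite)) if finite else float("nan")

    error_rate = float((total - np.trace(cm)) / total)
    return {
        "accuracy": float(np.trace(cm) / total),
        "precision": macro("precision"),
        "recall": macro("recall"),
        "specificity": macro("specificity"),
        "f1": macro("f1"),
        "error_rate": error_rate,
        "per_class": per_class,
    }


# ---------------------------------------------------------------------------
# Zone sequence logic
# ---------------------------------------------------------------------------

def count_switches(labels: np.ndarray) -> int:
    """Prediction-fluctuation count of a per-frame zone sequence.

    A clean stack transitions monotonically PCZ→CCZ→NSZ, each forward step
    at most once.  Every violation is a switch: a transition to a lower
    class, or a forward transition (a, b) already used earlier in the
    sequence.  A monotone sequence scores 0.
    """
    labels = np.asarray(labels)
    if labels.size and not np.isin(labels, [0, 1, 2]).all():
        raise ValueError("zone labels must be 0 (PCZ), 1 (CCZ) or 2 (NSZ)")
    switches = 0
    used_forward: set[tuple[int, int]] = set()
    for prev, cur in zip(labels[:-1], labels[1:]):
        if cur < prev:
            switches += 1
        elif cur > prev:
            step = (int(prev), int(cur))
            if step in used_forward:
                switches += 1
            else:
                used_forward.add(step)
    return switches


def ccz_range(labels: np.ndarray) -> tuple[int, int] | None:
    """Longest contiguous run of CCZ frames, as inclusive (first, last).

    Plugged-in classifiers can emit non-contiguous CCZ predictions; the
    longest run is retained (first such run on a tie).  None when no frame
    is CCZ.
    """
    labels = np.asarray(labels)
    is_ccz = labels == 1
    if not is_ccz.any():
        return None
    runs, n = ndimage.label(is_ccz)
    best, best_len = None, 0
    for run_id in range(1, n + 1):
        idx = np.nonzero(runs == run_id)[0]
        if len(idx) > best_len:
            best, best_len = (int(idx[0]), int(idx[-1])), len(idx)
    return best


def zone_labels_from_scores(scores: np.ndarray) -> ZoneLabels:
    """Argmax per-frame labels plus the CCZ range and switch count."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 3:
        raise ValueError(f"scores must be (frames, 3), got {scores.shape}")
    labels = scores.argmax(axis=1)
    return ZoneLabels(labels=labels, ccz=ccz_range(labels), switches=count_switches(labels))


# ---------------------------------------------------------------------------
# Rotation aggregation and padding-free crop
# ---------------------------------------------------------------------------

def aggregate_rotation(scores: np.ndarray, n_classes: int = 72, step_deg: float = 5.0) -> dict:
    """Stack-level rotation from per-frame class scores.

    Scores are averaged over frames; the argmax class c (lowest c on a tie)
    gives the predicted orientation c×step and the correction
    (360 − predicted) mod 360 to apply for alignment.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] == 0:
        raise ValueError(f"scores must be a non-empty (frames, classes) array, got {scores.shape}")
    if scores.shape[1] != n_classes:
        raise ValueError(f"expected {n_classes} classes, got {scores.shape[1]}")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    mean = scores.mean(axis=0)
    cls = int(mean.argmax())  # np.argmax returns the lowest index on ties
    predicted = cls * step_deg
    return {
        "class": cls,
        "predicted_angle_deg": float(predicted),
        "correction_deg": float((360.0 - predicted) % 360.0),
    }


def largest_rotated_rect(width: int, height: int, angle_deg: float) -> tuple[float, float]:
    """(crop_w, crop_h) of the maximum-area axis-aligned rectangle inside a
    W×H rectangle rotated by ``angle_deg``.  Closed form."""
    if width <= 0 or height <= 0:
        raise ValueError("width and height must be positive")
    angle = np.deg2rad(angle_deg % 180.0)
    sin_a, cos_a = abs(np.sin(angle)), abs(np.cos(angle))
    if sin_a < 1e-12:
        return float(width), float(height)
    if cos_a < 1e-12:
        return float(height), float(width)
    long_side, short_side = max(width, height), min(width, height)
    if short_side <= 2.0 * sin_a * cos_a * long_side or abs(sin_a - cos_a) < 1e-12:
        x = 0.5 * short_side
        if width >= height:
            return x / sin_a, x / cos_a
        return x / cos_a, x / sin_a
    cos_2a = cos_a * cos_a - sin_a * sin_a
    return (
        (width * cos_a - height * sin_a) / cos_2a,
        (height * cos_a - width * sin_a) / cos_2a,
    )


def _rotate_about_center(frame: np.ndarray, angle_deg: float, order: int = 0) -> np.ndarray:
    """Rotate content about the frame centre onto an enclosing odd-sized
    canvas, so the rotated footprint is centred on an exact pixel."""
    h, w = frame.shape
    a = np.deg2rad(angle_deg)
    sin_a, cos_a = abs(np.sin(a)), abs(np.cos(a))
    out_h = int(np.ceil(h * cos_a + w * sin_a))
    out_w = int(np.ceil(w * cos_a + h * sin_a))
    out_h += 1 - out_h % 2
    out_w += 1 - out_w % 2
    # output coordinate -> input coordinate: in = R @ (out - out_c) + in_c
    R = np.array([[np.cos(a), np.sin(a)], [-np.sin(a), np.cos(a)]])
    in_c = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    out_c = np.array([(out_h - 1) / 2.0, (out_w - 1) / 2.0])
    return ndimage.affine_transform(
        frame,
        R,
        offset=in_c - R @ out_c,
        output_shape=(out_h, out_w),
        order=order,
        mode="constant",
        cval=0,
    )


def rotate_and_crop_max_rect(frame: np.ndarray, angle_deg: float, order: int = 0) -> np.ndarray:
    """Rotate a 2D frame about its centre and crop the largest inscribed
    axis-aligned rectangle, so no padding pixel survives.

    A 256×256 frame rotated 45° yields a 181×181 crop (⌊256/√2⌋).  Nearest-
    neighbour resampling by default keeps label images and padding sentinels
    exact; pass ``order=1`` for bilinear on intensity frames.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2 or frame.size == 0:
        raise ValueError("frame must be a non-empty 2D array")
    if angle_deg % 90.0 == 0.0:
        # exact quarter turns: lossless, padding-free, full frame retained
        return np.rot90(frame, k=int(angle_deg // 90) % 4)
    h, w = frame.shape
    rotated = _rotate_about_center(frame, angle_deg, order=order)
    # a marker plane, resampled identically, flags every pixel that mixes in
    # any padding — guards the sub-pixel tangency of the inscribed rectangle
    marker = _rotate_about_center(np.ones((h, w)), angle_deg, order=order)
    crop_w, crop_h = largest_rotated_rect(w, h, angle_deg)
    cw, ch = max(int(np.floor(crop_w)), 1), max(int(np.floor(crop_h)), 1)

    def window(cw: int, ch: int) -> tuple[slice, slice]:
        # pixel-index centre of the rotated image is (n - 1) / 2
        cy, cx = (rotated.shape[0] - 1) / 2.0, (rotated.shape[1] - 1) / 2.0
        y0 = max(0, min(int(round(cy - (ch - 1) / 2.0)), rotated.shape[0] - ch))
        x0 = max(0, min(int(round(cx - (cw - 1) / 2.0)), rotated.shape[1] - cw))
        return slice(y0, y0 + ch), slice(x0, x0 + cw)

    ys, xs = window(cw, ch)
    while (cw > 1 or ch > 1) and not np.all(marker[ys, xs] >= 1.0 - 1e-9):
        cw, ch = max(cw - 1, 1), max(ch - 1, 1)
        ys, xs = window(cw, ch)
    return rotated[ys, xs]


# ---------------------------------------------------------------------------
# Tonotopic majority vote
# ---------------------------------------------------------------------------

def tonotopic_vote(
    frame_labels,
    scores: np.ndarray | None = None,
    window: int = 13,
) -> str:
    """Stack-level tonotopic region by majority vote over a median window.

    Votes are counted over ``window`` frames starting at the median frame
    index m = ⌊(F−1)/2⌋ and clipped at the stack end.  A tie goes to the
    label with the highest summed score inside the window when scores are
    given, else to the lowest class index.
    """
    labels = list(frame_labels)
    if not labels:
        raise ValueError("need at least one frame label")
    as_str = [
        lab if isinstance(lab, str) else TONOTOPIC_CLASSES[int(lab)] for lab in labels
    ]
    for lab in as_str:
        if lab not in TONOTOPIC_CLASSES:
            raise ValueError(f"unknown tonotopic label {lab!r}")
    m = (len(as_str) - 1) // 2
    sel = as_str[m : m + window]
    counts = {c: sel.count(c) for c in TONOTOPIC_CLASSES}
    top = max(counts.values())
    tied = [c for c in TONOTOPIC_CLASSES if counts[c] == top]
    if len(tied) == 1 or scores is None:
        return tied[0]
    scores = np.asarray(scores, dtype=float)
    window_scores = scores[m : m + window].sum(axis=0)
    best = max(tied, key=lambda c: window_scores[TONOTOPIC_CLASSES.index(c)])
    return best
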