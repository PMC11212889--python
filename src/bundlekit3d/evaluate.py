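"""3D instance-detection evaluation and agreement statistics.

Detection follows the volumetric IoU protocol: every ground-truth instance
is matched to the overlapping predicted instance of largest IoU (each
prediction consumed at most once), matched pairs with IoU ≥ t are true
positives, unmatched predictions false positives, unmatched ground truth
false negatives, swept over t ∈ {0.10, 0.15, …, 1.00}.  True negatives are
not counted — background dominates a 3D grid and would swamp the metric —
so the detection accuracy is TP/(TP+FP+FN), related to F1 = 2TP/(2TP+FP+FN)
by the exact identity  accuracy = F1/(2−F1).

Agreement statistics (Pearson r, paired t, Wilcoxon signed-rank,
Mann–Whitney U) and descriptives serve method-vs-observer comparisons of
measurement tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stackio import LabelVolume

__all__ = [
    "MatchResult",
    "iou3d",
    "match_instances",
    "sweep_thresholds",
    "detection_metrics",
    "accuracy_from_f1",
    "descriptives",
    "agreement",
]

IOU_THRESHOLDS = tuple(np.round(np.arange(0.10, 1.0001, 0.05), 2))


@dataclass
class MatchResult:
    iou_threshold: float
    pairs: list[tuple[int, int, float]]  # (gt_id, pred_id, IoU) of TPs
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else float("nan")

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else float("nan")

    @property
    def detection_accuracy(self) -> float:
        denom = self.tp + self.fp + self.fn
        return self.tp / denom if denom else float("nan")


def iou3d(vol_a: np.ndarray, vol_b: np.ndarray) -> float:
    """Volumetric Jaccard index |A∩B| / |A∪B| of two boolean supports."""
    a = np.asarray(vol_a, dtype=bool)
    b = np.asarray(vol_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"support shapes differ: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        raise ValueError("both supports empty: IoU undefined")
    return float(np.count_nonzero(a & b) / union)


def _pairwise_iou(gt: LabelVolume, pred: LabelVolume) -> dict[tuple[int, int], float]:
    """IoU of every overlapping (gt_id, pred_id) pair via a joint histogram."""
    g = gt.labels.ravel()
    p = pred.labels.ravel()
    both = (g > 0) | (p > 0)
    g, p = g[both], p[both]
    pairs, counts = np.unique(np.stack([g, p]), axis=1, return_counts=True)
    sizes_g = {int(i): int(c) for i, c in zip(*np.unique(g[g > 0], return_counts=True))}
    sizes_p = {int(i): int(c) for i, c in zip(*np.unique(p[p > 0], return_counts=True))}
    out = {}
    for (gi, pi), inter in zip(pairs.T, counts):
        gi, pi = int(gi), int(pi)
        if gi == 0 or pi == 0:
            continue
        union = sizes_g[gi] + sizes_p[pi] - int(inter)
        out[(gi, pi)] = int(inter) / union
    return out


def match_instances(gt: LabelVolume, pred: LabelVolume, iou_threshold: float = 0.5) -> MatchResult:
    """Match ground-truth to predicted instances by largest IoU.

    Candidate (gt, pred) pairs are taken in descending IoU order; each side
    is consumed at most once, so a ground-truth bundle split across two
    predictions keeps the larger-overlap prediction as its match and leaves
    the other as a false positive.  Matched pairs below the threshold count
    as both a false negative (the gt) and a false positive (the pred), which
    preserves TP+FN = #gt and TP+FP = #pred at every threshold.
    """
    if gt.shape != pred.shape:
        raise ValueError(f"volume shapes differ: {gt.shape} vs {pred.shape}")
    if not 0.0 < iou_threshold <= 1.0:
        raise ValueError(f"iou_threshold must lie in (0, 1], got {iou_threshold}")
    ious = _pairwise_iou(gt, pred)
    ranked = sorted(ious.items(), key=lambda kv: (-kv[1], kv[0]))
    used_gt: set[int] = set()
    used_pred: set[int] = set()
    matched: list[tuple[int, int, float]] = []
    for (gi, pi), iou in ranked:
        if gi in used_gt or pi in used_pred:
            continue
        used_gt.add(gi)
        used_pred.add(pi)
        matched.append((gi, pi, iou))
    tp_pairs = [m for m in matched if m[2] >= iou_threshold]
    n_gt = len(gt.id_set)
    n_pred = len(pred.id_set)
    tp = len(tp_pairs)
    return MatchResult(
        iou_threshold=iou_threshold,
        pairs=tp_pairs,
        tp=tp,
        fp=n_pred - tp,
        fn=n_gt - tp,
    )


def sweep_thresholds(gt: LabelVolume, pred: LabelVolume, thresholds=IOU_THRESHOLDS) -> pd.DataFrame:
    """Detection metrics across the IoU threshold sweep (0.10 … 1.00)."""
    rows = []
    for t in thresholds:
        r = match_instances(gt, pred, iou_threshold=float(t))
        rows.append(
            {
                "iou_threshold": float(t),
                "tp": r.tp, "fp": r.fp, "fn": r.fn,
                "precision": r.precision, "recall": r.recall,
                "f1": r.f1, "detection_accuracy": r.detection_accuracy,
            }
        )
    return pd.DataFrame.from_records(rows)


def detection_metrics(tp: int, fp: int, fn: int) -> dict:
    """Precision/recall/F1/accuracy from raw match counts."""
    r = MatchResult(iou_threshold=float("nan"), pairs=[], tp=tp, fp=fp, fn=fn)
    return {
        "precision": r.precision,
        "recall": r.recall,
        "f1": r.f1,
        "detection_accuracy": r.detection_accuracy,
    }


def accuracy_from_f1(f1: float) -> float:
    """Detection accuracy implied by a balanced F1 via acc = F1/(2−F1).

    Exact consequence of acc = TP/(TP+FP+FN) and F1 = 2TP/(2TP+FP+FN).
    """
    if not 0.0 <= f1 <= 1.0:
        raise ValueError(f"F1 must lie in [0, 1], got {f1}")
    return f1 / (2.0 - f1)


# ---------------------------------------------------------------------------
# Descriptive and agreement statistics
# ---------------------------------------------------------------------------

def descriptives(values, population_std: bool = True) -> dict:
    """Mean, median and standard deviation of one column.

    The population (divisor n) standard deviation is the default; pass
    ``population_std=False`` for the n−1 sample estimator.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("descriptives of an empty sample")
    return {
        "mean": float(arr.mean()),
        "median": float(np.median(arr)),
        "std": float(arr.std(ddof=0 if population_std else 1)),
        "n": int(arr.size),
    }


def agreement(x, y, tests=("pearson", "paired_t")) -> dict:
    """Agreement statistics between two paired measurement columns.

    Available tests: ``pearson``, ``paired_t`` (df = n−1), ``wilcoxon``
    (signed-rank, zero differences dropped, exact distribution for n ≤ 25
    without ties), ``mannwhitney``.  All p-values two-sided.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    paired = {"pearson", "paired_t", "wilcoxon"}
    if any(t in paired for t in tests) and x.size != y.size:
        raise ValueError("paired tests require equal-length samples")
    if x.size < 3 or y.size < 3:
        raise ValueError("need at least 3 observations per sample")
    out: dict = {"n": int(x.size)}
    for test in tests:
        if test == "pearson":
            if np.std(x) == 0 or np.std(y) == 0:
                out["pearson_r"], out["pearson_p"] = float("nan"), float("nan")
                out["pearson_note"] = "zero-variance input"
            else:
                r, p = stats.pearsonr(x, y)
                out["pearson_r"], out["pearson_p"] = float(r), float(p)
        elif test == "paired_t":
            if np.all(x == y):
                t, p = 0.0, 1.0  # identical measurements: no difference to test
            else:
                t, p = stats.ttest_rel(x, y)
            out["paired_t"], out["t_p"], out["df"] = float(t), float(p), int(x.size - 1)
        elif test == "wilcoxon":
            diff = x - y
            if np.all(diff == 0):
                out["wilcoxon_W"], out["w_p"] = 0.0, 1.0
                out["wilcoxon_note"] = "all differences zero"
            else:
                w, p = stats.wilcoxon(x, y, zero_method="wilcox", mode="auto")
                out["wilcoxon_W"], out["w_p"] = float(w), float(p)
        elif test == "mannwhitney":
            u, p = stats.mannwhitneyu(x, y, alternative="two-sided")
            out["mannwhitney_U"], out["mw_p"] = float(u), float(p)
        else:
            raise ValueError(f"unknown test {test!r}")
    return out
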