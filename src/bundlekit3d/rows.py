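"""Row identity (IHC, OHC1, OHC2, OHC3) from base-point geometry.

After planar-cell-polarity alignment the four rows run horizontally with the
inner-hair-cell row bottom-most (largest image y).  Clustering the bundles'
base-point y-coordinates into k=4 groups and ordering cluster means by
descending y therefore recovers row identity: IHC, then OHC1, OHC2, OHC3.

Two interchangeable backends: KMeans (fast, spherical clusters) and a
Gaussian mixture (per-row variances may differ).  An ``external`` method
accepts labels produced elsewhere, e.g. by a learned classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .phantoms import ROW_LABELS

__all__ = ["RowAssignment", "row_assign", "order_clusters"]


@dataclass
class RowAssignment:
    labels: dict[int, str]          # bundle id -> row label
    method: str
    cluster_means: list[float]      # descending y, aligned with ROW_LABELS

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": list(self.labels), "row": list(self.labels.values())}
        ).sort_values("id", ignore_index=True)


def order_clusters(cluster_means: Sequence[float], k: int | None = None) -> dict[int, str]:
    """Map cluster indices to row labels by strictly descending mean y.

    The largest-mean cluster is IHC (bottom-most row), then OHC1..OHC3.
    Tied means indicate a degenerate clustering and raise ValueError.
    """
    means = np.asarray(cluster_means, dtype=float)
    k = k if k is not None else len(means)
    if len(means) != k:
        raise ValueError(f"expected {k} cluster means, got {len(means)}")
    if len(np.unique(means)) != len(means):
        raise ValueError(f"tied cluster means {means.tolist()}: degenerate clustering")
    order = np.argsort(-means)  # descending y
    return {int(cluster): ROW_LABELS[rank] for rank, cluster in enumerate(order)}


def row_assign(
    points: Mapping[int, tuple[float, float]] | pd.DataFrame,
    method: str = "kmeans",
    k: int = 4,
    seed: int = 0,
    use_xy: bool = False,
) -> RowAssignment:
    """Cluster bundle base points into rows.

    Parameters
    ----------
    points
        Either ``{bundle_id: (x, y)}`` or a DataFrame with columns
        ``id, x2, y2`` (the base endpoints of the height table).
    method
        ``kmeans`` or ``gmm``.
    use_xy
        Cluster on (x, y) instead of the default y-only feature.
    """
    if isinstance(points, pd.DataFrame):
        ids = [int(i) for i in points["id"]]
        xy = points[["x2", "y2"]].to_numpy(dtype=float)
    else:
        ids = [int(i) for i in points]
        xy = np.array([points[i] for i in ids], dtype=float)
    if len(ids) < k:
        raise ValueError(
            f"{len(ids)} bundles cannot form {k} rows; use k <= {len(ids)}"
        )
    if not np.isfinite(xy).all():
        raise ValueError("base points must be finite")

    features = xy if use_xy else xy[:, 1:2]
    if method == "kmeans":
        model = KMeans(n_clusters=k, n_init=10, random_state=seed)
        assigned = model.fit_predict(features)
        means_y = model.cluster_centers_[:, -1]
    elif method == "gmm":
        model = GaussianMixture(
            n_components=k, n_init=5, random_state=seed, covariance_type="full"
        )
        assigned = model.fit_predict(features)
        means_y = model.means_[:, -1]
    else:
        raise ValueError(f"unknown method {method!r}; use 'kmeans' or 'gmm'")

    mapping = order_clusters(means_y, k)
    labels = {i: mapping[int(c)] for i, c in zip(ids, assigned)}
    ordered_means = sorted((float(m) for m in means_y), reverse=True)
    return RowAssignment(labels=labels, method=method, cluster_means=ordered_means)
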