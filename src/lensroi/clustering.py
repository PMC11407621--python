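"""Activity clustering of ROI traces.

ROI determination deliberately over-segments (uniform coverage avoids
missing faint activity), so many ROIs contain no responsive neuron.
Clustering the traces separates the activity patterns: traces are
averaged into minute-scale temporal bins (the patterns differ on the
scale of minutes; binning suppresses frame-level noise), centered and
soft-normalized (divided by their standard deviation plus a
noise-floor offset, so active traces are compared by shape while
silent ones collapse toward the origin instead of being inflated into
random unit vectors), reduced by PCA to the components explaining 95%
of the variance, and grouped by k-means; the number of clusters is
chosen by the maximum mean silhouette score over a candidate range.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)


@dataclass
class TraceReduction:
    """PCA scores of (z-scored) ROI traces."""

    scores: np.ndarray  # n_kept x n_components
    kept: np.ndarray  # indices of traces that survived the variance filter
    explained_variance_ratio: np.ndarray
    n_components: int


@dataclass
class ClusterResult:
    """Silhouette-selected k-means partition of ROI traces."""

    labels: np.ndarray  # 1-based cluster labels, one per clustered trace
    k: int
    silhouette_by_k: dict[int, float]
    n_components: int
    cluster_mean_traces: np.ndarray | None = None  # k x T, in input trace units


def reduce_traces(
    traces: np.ndarray,
    variance_threshold: float = 0.95,
    standardize: bool = True,
    n_bins: int | None = 60,
) -> TraceReduction:
    """Project traces onto the leading principal components.

    Traces are first averaged into ``n_bins`` equal temporal bins
    (60 by default, i.e. one bin per minute of a one-hour window at
    10 fps): the activity patterns differ on the scale of minutes, and
    binning suppresses frame-level noise that would otherwise dominate
    Euclidean distances.  Traces shorter than ``n_bins`` frames are
    used as-is.

    Binned traces are then centered and divided by ``sd + floor``
    where ``floor`` is the median per-trace standard deviation: active
    traces of different amplitudes (depths) are compared by shape,
    while near-silent traces shrink toward the origin rather than
    being blown up to unit variance.  Zero-variance traces are dropped
    with a warning.  The smallest component set whose cumulative
    explained variance reaches ``variance_threshold`` is retained.
    """
    traces = np.asarray(traces, dtype=np.float64)
    if traces.ndim != 2 or traces.shape[0] < 2:
        raise ValueError("need at least 2 traces")
    if not 0 < variance_threshold <= 1.0:
        raise ValueError("variance_threshold must be in (0, 1]")
    if n_bins is not None and n_bins < traces.shape[1]:
        t = traces.shape[1] - (traces.shape[1] % n_bins)
        traces = traces[:, :t].reshape(traces.shape[0], n_bins, -1).mean(axis=2)
    sd = traces.std(axis=1)
    kept = np.flatnonzero(sd > 0)
    if kept.size < traces.shape[0]:
        dropped = traces.shape[0] - kept.size
        warnings.warn(f"dropping {dropped} zero-variance trace(s) before PCA")
    if kept.size < 2:
        raise ValueError("fewer than 2 traces with nonzero variance")
    x = traces[kept]
    if standardize:
        floor = float(np.median(sd[kept]))
        x = (x - x.mean(axis=1, keepdims=True)) / (sd[kept] + floor)[:, None]
    pca = PCA(svd_solver="full")
    all_scores = pca.fit_transform(x)
    cumulative = np.cumsum(pca.explained_variance_ratio_)
    n_components = int(np.searchsorted(cumulative, variance_threshold - 1e-12) + 1)
    n_components = min(n_components, all_scores.shape[1])
    return TraceReduction(
        scores=all_scores[:, :n_components],
        kept=kept,
        explained_variance_ratio=pca.explained_variance_ratio_[:n_components],
        n_components=n_components,
    )


def cluster_traces(
    scores: np.ndarray | TraceReduction,
    k_min: int = 2,
    k_max: int = 10,
    seed: int = 0,
    n_init: int = 10,
) -> ClusterResult:
    """k-means over a candidate k range, selected by mean silhouette.

    Ties in the silhouette score break toward the smallest k.  The
    candidate range is capped at n_samples - 1 (the silhouette score
    requires at least one sample outside each cluster).
    """
    reduction = scores if isinstance(scores, TraceReduction) else None
    x = reduction.scores if reduction is not None else np.asarray(scores, float)
    if x.ndim != 2:
        raise ValueError("scores must be 2-D (samples x features)")
    n = x.shape[0]
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    if n < k_min + 1:
        raise ValueError(f"too few samples ({n}) for k_min={k_min}")
    if np.allclose(x, x[0]):
        raise ValueError("all samples identical; clustering is degenerate")
    k_max = min(k_max, n - 1)

    silhouettes: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in range(k_min, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(x)
        if len(np.unique(labels)) < 2:
            continue
        silhouettes[k] = float(silhouette_score(x, labels))
        labels_by_k[k] = labels
    if not silhouettes:
        raise ValueError("no candidate k produced a valid partition")
    best_k = max(sorted(silhouettes), key=lambda k: silhouettes[k])
    # sorted() + max keeps the smallest k on ties because max returns the
    # first maximal element
    return ClusterResult(
        labels=labels_by_k[best_k] + 1,
        k=best_k,
        silhouette_by_k=silhouettes,
        n_components=x.shape[1],
    )


def attach_mean_traces(result: ClusterResult, traces: np.ndarray) -> ClusterResult:
    """Compute per-cluster mean traces (in the units of ``traces``)."""
    traces = np.asarray(traces, dtype=np.float64)
    means = np.vstack(
        [traces[result.labels == lab].mean(axis=0) for lab in range(1, result.k + 1)]
    )
    result.cluster_mean_traces = means
    return result


def active_cluster(
    result: ClusterResult,
    traces: np.ndarray,
    start_frame: int = 0,
) -> int:
    """Cluster whose members have the highest time-averaged mean trace.

    ``traces`` must align row-wise with ``result.labels``; the average
    is taken from ``start_frame`` on (e.g. the post-stimulation window).
    Ties break toward the smallest label.
    """
    traces = np.asarray(traces, dtype=np.float64)
    if traces.shape[0] != result.labels.shape[0]:
        raise ValueError("traces do not align with cluster labels")
    means = np.array(
        [
            traces[result.labels == lab, start_frame:].mean()
            for lab in range(1, result.k + 1)
        ]
    )
    return int(np.argmax(means)) + 1
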