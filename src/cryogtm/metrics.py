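"""Clustering-quality statistics for view-based ground truth.

A good 2D classification groups images that were projected along nearby
directions, so the pooled distribution of pairwise great-circle angles
between the ground-truth view directions of same-class images ("angular
distances") concentrates near zero.  The in-plane angle is excluded: the
metric concerns viewing-direction homogeneity only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._errors import DataError

__all__ = [
    "AngularHistogram",
    "angular_distance",
    "pairwise_class_distances",
    "class_angular_histogram",
    "rank_class_sizes",
    "effective_class_count",
    "purity",
]


@dataclass(frozen=True)
class AngularHistogram:
    """Normalised histogram of pooled within-class angular distances."""

    edges: np.ndarray = field(repr=False)  # degrees, len = bins + 1
    frequencies: np.ndarray = field(repr=False)  # sums to 1
    n_pairs: int
    mean: float  # mean pooled distance, degrees


def angular_distance(view_a, view_b) -> float:
    """Great-circle angle between two unit view vectors, in degrees."""
    a = np.asarray(view_a, dtype=float)
    b = np.asarray(view_b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DataError("zero-length view vector")
    cos = np.clip(np.dot(a / na, b / nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def pairwise_class_distances(labels, views) -> np.ndarray:
    """All C(n_k, 2) within-class angular distances pooled over classes."""
    labels = np.asarray(labels)
    views = np.asarray(views, dtype=float)
    if labels.shape[0] != views.shape[0]:
        raise DataError("labels and views must align by image index")
    norms = np.linalg.norm(views, axis=1)
    if np.any(norms == 0):
        raise DataError("zero-length view vector")
    unit = views / norms[:, None]
    chunks = []
    for lab in np.unique(labels):
        v = unit[labels == lab]
        n = v.shape[0]
        if n < 2:
            continue
        cos = np.clip(v @ v.T, -1.0, 1.0)
        iu = np.triu_indices(n, k=1)
        chunks.append(np.degrees(np.arccos(cos[iu])))
    if not chunks:
        return np.empty(0)
    return np.concatenate(chunks)


def class_angular_histogram(labels, views, bins=None) -> AngularHistogram:
    """Histogram the pooled within-class angular distances.

    Default bins are 1 degree wide over [0, 180]; frequencies are
    normalised to unit sum.  Classes of size < 2 contribute no pairs.
    """
    if bins is None:
        bins = np.arange(0.0, 181.0, 1.0)
    dists = pairwise_class_distances(labels, views)
    counts, edges = np.histogram(dists, bins=bins)
    total = counts.sum()
    freq = counts / total if total > 0 else counts.astype(float)
    mean = float(dists.mean()) if dists.size else float("nan")
    return AngularHistogram(
        edges=edges, frequencies=freq, n_pairs=int(dists.size), mean=mean
    )


def rank_class_sizes(labels, k: int) -> np.ndarray:
    """Class sizes sorted descending, length k (zeros for empty classes)."""
    labels = np.asarray(labels)
    if labels.size and (labels.min() < 0 or labels.max() >= k):
        raise DataError(f"labels must lie in [0, {k})")
    sizes = np.bincount(labels, minlength=k)
    return np.sort(sizes)[::-1]


def effective_class_count(labels) -> int:
    """Number of classes with at least one hard-assigned image."""
    return int(np.unique(np.asarray(labels)).size)


def purity(labels, truth) -> float:
    """Majority-vote purity: sum of per-class majority counts over N."""
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    if labels.shape != truth.shape:
        raise DataError("labels and ground-truth ids must align by image index")
    total = 0
    for lab in np.unique(labels):
        _, counts = np.unique(truth[labels == lab], return_counts=True)
        total += counts.max()
    return total / labels.size
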