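"""Unsupervised grasp recognition: K-means with subject-seeded centroids.

The experiment protocol: each of a panel's subjects in turn provides the
cluster centroid starting locations — the average over that subject's
repetitions of each grasp type — and K-means (Lloyd iterations under the
squared Euclidean distance d(x, c) = (x - c)(x - c)') clusters the poses of
the *remaining* subjects.  Because cluster j is seeded from grasp type j,
cluster identities are fixed and never re-ordered, so a confusion matrix
(true grasp type x recognized cluster) is directly meaningful.  Relative
accuracy is the per-type diagonal fraction, absolute accuracy the overall
diagonal fraction.

Implementation choices where the protocol is underspecified: convergence is
declared when the assignment vector is unchanged between iterations (with a
max-iteration safety bound); a cluster that loses all members keeps its
previous centroid, preserving its identity; distance ties go to the
lowest-indexed centroid.  The algorithm is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .synthetic import GraspPanel


@dataclass(frozen=True)
class KMeansConfig:
    """Lloyd-iteration settings; the distance is fixed to squared Euclidean."""

    n_clusters: int = 8
    max_iter: int = 100
    update_centroids: bool = True   # False = one-shot nearest-centroid classification

    def __post_init__(self):
        if self.n_clusters < 1 or self.max_iter < 1:
            raise ValueError("n_clusters and max_iter must be >= 1")


@dataclass(frozen=True)
class ConfusionMatrix:
    """k x k counts: rows = true grasp type, columns = recognized cluster."""

    counts: np.ndarray = field(repr=False)
    labels: tuple[int, ...] = ()

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=int)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if np.any(counts < 0):
            raise ValueError("counts must be >= 0")
        labels = self.labels or tuple(range(1, counts.shape[0] + 1))
        if len(labels) != counts.shape[0]:
            raise ValueError("labels must match matrix size")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "labels", tuple(labels))

    @property
    def k(self) -> int:
        return self.counts.shape[0]


def _assign(samples: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    # squared Euclidean distances; argmin takes the lowest index on ties
    d2 = ((samples[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def kmeans_fixed_init(samples, init_centroids, config: KMeansConfig | None = None):
    """Lloyd's algorithm from fixed, labeled starting centroids.

    Parameters
    ----------
    samples
        n x d array of poses.
    init_centroids
        k x d array; cluster j inherits its identity from row j and is never
        re-ordered.
    config
        Iteration settings; with ``update_centroids=False`` only the initial
        assignment pass runs (nearest-centroid classification).

    Returns
    -------
    (assignments, final_centroids, n_iter)
        Cluster index per sample, final k x d centroids, and the number of
        assignment passes performed.
    """
    samples = np.asarray(samples, dtype=float)
    centroids = np.array(init_centroids, dtype=float)
    if samples.ndim != 2 or centroids.ndim != 2 or samples.shape[1] != centroids.shape[1]:
        raise ValueError(
            f"dimension mismatch: samples {samples.shape} vs centroids {centroids.shape}"
        )
    if samples.shape[0] == 0:
        raise ValueError("samples must be nonempty")
    config = config or KMeansConfig(n_clusters=centroids.shape[0])
    if centroids.shape[0] != config.n_clusters:
        raise ValueError("init_centroids row count must equal n_clusters")

    assignments = _assign(samples, centroids)
    n_iter = 1
    if not config.update_centroids:
        return assignments, centroids, n_iter
    for _ in range(config.max_iter - 1):
        for j in range(config.n_clusters):
            members = samples[assignments == j]
            if members.shape[0]:          # empty cluster keeps its centroid
                centroids[j] = members.mean(axis=0)
        new_assignments = _assign(samples, centroids)
        n_iter += 1
        if np.array_equal(new_assignments, assignments):
            break
        assignments = new_assignments
    return assignments, centroids, n_iter


def loocv_recognition(panel: GraspPanel, config: KMeansConfig | None = None):
    """Leave-one-subject-out recognition over a balanced grasp panel.

    For each held-out subject s, the centroid of cluster g starts at the
    mean of s's repetitions of grasp g; all poses of the other subjects are
    then clustered and tallied into a confusion matrix (true label x
    recognized cluster).

    Returns
    -------
    list of (held_out_subject, ConfusionMatrix)
        One entry per subject, in ascending subject order.

    Raises
    ------
    ValueError
        If the panel has fewer than 2 subjects, is unbalanced, or a subject
        lacks repetitions of some grasp type.
    """
    subjects = panel.subjects
    labels = panel.labels
    if subjects.size < 2:
        raise ValueError("LOOCV needs at least 2 subjects")
    if not panel.is_balanced():
        raise ValueError("panel must be balanced (same repetition count per subject/label)")
    k = labels.size
    config = config or KMeansConfig(n_clusters=k)
    if config.n_clusters != k:
        raise ValueError(f"config.n_clusters={config.n_clusters} but panel has {k} grasp types")

    results = []
    for s in subjects:
        centroids = []
        for g in labels:
            mask = (panel.subject_id == s) & (panel.grasp_label == g)
            if not mask.any():
                raise ValueError(f"subject {s} has no repetitions of grasp {g}")
            centroids.append(panel.poses[mask].mean(axis=0))
        rest = panel.subject_id != s
        samples = panel.poses[rest]
        true = panel.grasp_label[rest]
        assignments, _, _ = kmeans_fixed_init(samples, np.array(centroids), config)
        counts = np.zeros((k, k), dtype=int)
        label_pos = {g: i for i, g in enumerate(labels.tolist())}
        for t, a in zip(true, assignments):
            counts[label_pos[t], a] += 1
        results.append((int(s), ConfusionMatrix(counts=counts, labels=tuple(labels.tolist()))))
    return results


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def accuracy_report(cm: ConfusionMatrix, decimals: int | None = 2):
    """Relative (per grasp type) and absolute accuracy percentages.

    relative_g = 100 * counts[g, g] / row_sum_g;
    absolute   = 100 * trace / total.
    Rounded half-up to ``decimals`` places (None = unrounded).

    Raises
    ------
    ValueError
        If any row sum is zero (no held-out samples of that grasp type).
    """
    counts = cm.counts
    row_sums = counts.sum(axis=1)
    if np.any(row_sums == 0):
        empty = [cm.labels[i] for i in np.flatnonzero(row_sums == 0)]
        raise ValueError(f"no samples for grasp type(s) {empty}")
    relative = 100.0 * np.diag(counts) / row_sums
    absolute = 100.0 * np.trace(counts) / counts.sum()
    if decimals is not None:
        relative = np.array([_round_half_up(v, decimals) for v in relative])
        absolute = _round_half_up(absolute, decimals)
    return relative, float(absolute)
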