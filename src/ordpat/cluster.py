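"""Two-class k-means on motif-frequency features, with max-min initialisation.

The clustering is deliberately plain and fully deterministic: the first
record in dataset order seeds one centroid, the record farthest from it (in
Euclidean distance) seeds the other, and a fixed number of assign/update
rounds follows, closed by a final assignment pass.  Determinism makes the
unsupervised accuracy of a feature set directly comparable across feature
choices (scalar permutation entropy vs the full frequency vector), which is
the point of the pipeline.

Accuracy of an unsupervised 2-partition is scored under the best of the two
cluster-to-class bijections.  A leave-one-out protocol repeatedly omits one
record per class, refits, and classifies the omitted records by nearest
final centroid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "KMeansResult",
    "AccuracyReport",
    "LOOReport",
    "maxmin_init",
    "kmeans",
    "threshold_accuracy",
    "cluster_accuracy",
    "label_centroids",
    "classify_nearest_centroid",
    "loo_evaluate",
]


@dataclass(frozen=True)
class FeatureMatrix:
    """Ordered records with a shared feature dimension.

    Order is meaningful: max-min initialisation seeds from the first record.
    """

    ids: tuple[str, ...]
    labels: tuple | None
    X: np.ndarray

    def __post_init__(self):
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "ids", tuple(self.ids))
        if self.labels is not None:
            object.__setattr__(self, "labels", tuple(self.labels))
            if len(self.labels) != X.shape[0]:
                raise ValueError("labels length must match number of records")
        if len(self.ids) != X.shape[0]:
            raise ValueError("ids length must match number of records")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, feature_columns: list[str],
                       id_column: str = "record_id", label_column: str | None = "label"):
        labels = tuple(df[label_column]) if label_column and label_column in df else None
        return cls(ids=tuple(str(v) for v in df[id_column]), labels=labels,
                   X=df[feature_columns].to_numpy(dtype=float))


@dataclass(frozen=True)
class KMeansResult:
    centroids: np.ndarray
    assignments: np.ndarray
    iterations_run: int
    inertia_history: tuple[float, ...]


@dataclass(frozen=True)
class AccuracyReport:
    """Best-bijection accuracy of a 2-cluster partition against true labels."""

    accuracy: float  # percent
    confusion: np.ndarray  # rows: true class, cols: mapped predicted class
    classes: tuple
    mapping: tuple[int, ...]  # mapping[cluster] = class index
    per_class_errors: dict
    accuracy_sd: float = 0.0


@dataclass(frozen=True)
class LOOReport:
    accuracy: float  # percent over all held-out classifications
    per_class_accuracy: dict
    per_class_errors: dict
    realisations: int
    log: pd.DataFrame = field(repr=False, default=None)


def _distances(X: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    return np.linalg.norm(X[:, None, :] - centroids[None, :, :], axis=2)


def maxmin_init(features: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Two seed centroids: the first record, and the record farthest from it.

    Distance ties resolve to the lowest record index (``argmax`` semantics).
    """
    X = features.X if isinstance(features, FeatureMatrix) else np.atleast_2d(np.asarray(features, float))
    if X.shape[0] < 2:
        raise ValueError("max-min initialisation needs at least 2 records")
    c1 = X[0]
    far = int(np.argmax(np.linalg.norm(X - c1, axis=1)))
    return np.vstack([c1, X[far]])


def kmeans(features: FeatureMatrix | np.ndarray, k: int = 2, iterations: int = 10,
           *, init: np.ndarray | None = None) -> KMeansResult:
    """Fixed-budget k-means under the Euclidean metric.

    ``iterations`` assign/update rounds run after initialisation, followed by
    one final assignment pass, so the returned assignment is consistent with
    the returned centroids.  Empty clusters keep their previous centroid.
    Assignment ties go to the lower-index centroid.  The whole procedure is
    deterministic given record order.
    """
    X = features.X if isinstance(features, FeatureMatrix) else np.atleast_2d(np.asarray(features, float))
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} records, got {X.shape[0]}")
    if init is None:
        if k != 2:
            raise ValueError("max-min initialisation is defined for k=2; pass init= for other k")
        centroids = maxmin_init(X)
    else:
        centroids = np.array(init, dtype=float, copy=True)
        if centroids.shape != (k, X.shape[1]):
            raise ValueError("init must have shape (k, d)")
    inertia = []
    assignments = None
    for _ in range(iterations):
        dist = _distances(X, centroids)
        assignments = np.argmin(dist, axis=1)
        inertia.append(float(np.sum(np.min(dist, axis=1) ** 2)))
        for c in range(k):
            members = X[assignments == c]
            if members.shape[0]:
                centroids[c] = members.mean(axis=0)
            else:
                logger.info("cluster %d empty; keeping previous centroid", c)
    dist = _distances(X, centroids)
    assignments = np.argmin(dist, axis=1)
    inertia.append(float(np.sum(np.min(dist, axis=1) ** 2)))
    return KMeansResult(
        centroids=centroids,
        assignments=assignments,
        iterations_run=iterations,
        inertia_history=tuple(inertia),
    )


def _class_order(labels) -> list:
    seen: list = []
    for v in labels:
        if v not in seen:
            seen.append(v)
    return seen


def cluster_accuracy(assignments, labels) -> AccuracyReport:
    """Score a 2-cluster assignment against two true classes.

    The accuracy is the maximum over the two cluster->class bijections of
    the fraction of records whose mapped cluster equals their true class,
    expressed as a percentage.  The confusion matrix is reported under the
    maximising mapping (rows: true class, columns: predicted class, both in
    first-appearance class order).
    """
    assignments = np.asarray(assignments)
    labels = list(labels)
    if len(labels) != assignments.size:
        raise ValueError("labels and assignments must have equal length")
    classes = _class_order(labels)
    if len(classes) > 2:
        raise ValueError(f"only two-class scoring is supported, got classes {classes}")
    y = np.array([classes.index(v) for v in labels])
    best = None
    for mapping in ((0, 1), (1, 0)):
        pred = np.array([mapping[a] for a in assignments])
        correct = int(np.sum(pred == y))
        if best is None or correct > best[0]:
            best = (correct, mapping, pred)
    correct, mapping, pred = best
    ncls = len(classes)
    confusion = np.zeros((ncls, ncls), dtype=int)
    for t, p in zip(y, pred):
        confusion[t, min(p, ncls - 1)] += 1
    per_class_errors = {
        cls: int(np.sum((y == i) & (pred != i))) for i, cls in enumerate(classes)
    }
    return AccuracyReport(
        accuracy=100.0 * correct / assignments.size,
        confusion=confusion,
        classes=tuple(classes),
        mapping=mapping,
        per_class_errors=per_class_errors,
    )


def threshold_accuracy(values, labels) -> AccuracyReport:
    """Best-threshold accuracy of a scalar feature against two classes.

    The classifier is a single cut point on the feature axis: records below
    the cut go to one class, the rest to the other.  The reported accuracy
    is the maximum, over all cut positions and both class orientations, of
    the fraction classified correctly (resubstitution accuracy of the
    optimal threshold).  This is the standard way a scalar complexity index
    such as permutation entropy is used as a single classification feature,
    and it upper-bounds what any fixed threshold could achieve on the data.
    """
    v = np.asarray(values, dtype=float).ravel()
    labels = list(labels)
    if len(labels) != v.size:
        raise ValueError("labels and values must have equal length")
    classes = _class_order(labels)
    if len(classes) > 2:
        raise ValueError(f"only two-class scoring is supported, got classes {classes}")
    y = np.array([classes.index(l) for l in labels])
    order = np.argsort(v, kind="stable")
    ys = y[order]
    tot1 = int(ys.sum())
    n = v.size
    best = None
    cum = np.concatenate([[0], np.cumsum(ys)])
    for cut in range(n + 1):
        left1 = int(cum[cut])
        right1 = tot1 - left1
        left0 = cut - left1
        right0 = (n - cut) - right1
        for mapping, correct in (((0, 1), left0 + right1), ((1, 0), left1 + right0)):
            if best is None or correct > best[0]:
                best = (correct, cut, mapping)
    correct, cut, mapping = best
    pred = np.empty(n, dtype=int)
    pred[order[:cut]] = mapping[0]
    pred[order[cut:]] = mapping[1]
    ncls = len(classes)
    confusion = np.zeros((ncls, ncls), dtype=int)
    for t, p in zip(y, pred):
        confusion[t, min(p, ncls - 1)] += 1
    per_class_errors = {
        cls: int(np.sum((y == i) & (pred != i))) for i, cls in enumerate(classes)
    }
    return AccuracyReport(
        accuracy=100.0 * correct / n,
        confusion=confusion,
        classes=tuple(classes),
        mapping=mapping,
        per_class_errors=per_class_errors,
    )


def label_centroids(assignments, labels, k: int = 2) -> list:
    """Class tag for each centroid: majority class of its members.

    Ties (and empty clusters) fall back to the first class in first-
    appearance order.
    """
    labels = list(labels)
    classes = _class_order(labels)
    out = []
    assignments = np.asarray(assignments)
    for c in range(k):
        member_labels = [labels[i] for i in np.flatnonzero(assignments == c)]
        if not member_labels:
            out.append(classes[0])
            continue
        counts = [(member_labels.count(cls), -classes.index(cls)) for cls in classes]
        out.append(classes[max(range(len(classes)), key=lambda i: counts[i])])
    return out


def classify_nearest_centroid(vector, centroids, centroid_labels):
    """Label of the Euclidean-nearest centroid (ties: lower-index centroid)."""
    v = np.asarray(vector, dtype=float).ravel()
    d = np.linalg.norm(np.atleast_2d(centroids) - v, axis=1)
    return centroid_labels[int(np.argmin(d))]


def loo_evaluate(features: FeatureMatrix, realisations: int = 100,
                 rng: np.random.Generator | None = None, *,
                 iterations: int = 10) -> LOOReport:
    """Leave-one-out-per-class evaluation of the clustering pipeline.

    Each realisation omits one record from each class, drawn uniformly (with
    replacement across realisations), refits 2-means on the remaining
    records in their original order, labels the final centroids by member
    majority, and classifies the two omitted records by nearest centroid.
    """
    if rng is None:
        rng = np.random.default_rng()
    if realisations < 1:
        raise ValueError("realisations must be >= 1")
    if features.labels is None:
        raise ValueError("leave-one-out evaluation requires labels")
    labels = list(features.labels)
    classes = _class_order(labels)
    if len(classes) != 2:
        raise ValueError("exactly two classes are required")
    idx_by_class = {cls: np.flatnonzero([v == cls for v in labels]) for cls in classes}
    for cls, idx in idx_by_class.items():
        if idx.size < 2:
            raise ValueError(f"class {cls!r} needs at least 2 records")
    rows = []
    correct_by_class = {cls: 0 for cls in classes}
    total_by_class = {cls: 0 for cls in classes}
    for r in range(realisations):
        held = [int(rng.choice(idx_by_class[cls])) for cls in classes]
        keep = np.array([i for i in range(features.n) if i not in held])
        sub_X = features.X[keep]
        sub_labels = [labels[i] for i in keep]
        res = kmeans(sub_X, k=2, iterations=iterations)
        cent_labels = label_centroids(res.assignments, sub_labels, k=2)
        for cls, i in zip(classes, held):
            pred = classify_nearest_centroid(features.X[i], res.centroids, cent_labels)
            ok = pred == cls
            correct_by_class[cls] += int(ok)
            total_by_class[cls] += 1
            rows.append({
                "realisation": r,
                "record_id": features.ids[i],
                "true_class": cls,
                "predicted_class": pred,
                "correct": bool(ok),
            })
    log = pd.DataFrame(rows)
    total = sum(total_by_class.values())
    correct = sum(correct_by_class.values())
    return LOOReport(
        accuracy=100.0 * correct / total,
        per_class_accuracy={
            cls: 100.0 * correct_by_class[cls] / total_by_class[cls] for cls in classes
        },
        per_class_errors={
            cls: total_by_class[cls] - correct_by_class[cls] for cls in classes
        },
        realisations=realisations,
        log=log,
    )
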