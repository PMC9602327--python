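"""Nearest-neighbor family classification in ANV space.

A query sequence is assigned the class of its nearest training vector under
Euclidean distance (k = 1 by default; general k uses a majority vote).
Evaluation is leave-one-out: each vector is classified against all the
others, which is the only protocol under which a shared train/test set can
yield an informative accuracy below 100%. The naive protocol that lets a
vector match itself is available via ``include_self`` for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "LabeledVectors",
    "AccuracyReport",
    "NearestNeighborFamilyClassifier",
    "nearest_neighbor",
    "leave_one_out_evaluate",
]


@dataclass(frozen=True)
class LabeledVectors:
    """n vectors with class labels and sequence identifiers."""

    vectors: np.ndarray
    labels: tuple[str, ...]
    ids: tuple[str, ...]

    def __post_init__(self):
        vecs = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        object.__setattr__(self, "vectors", vecs)
        object.__setattr__(self, "labels", tuple(map(str, self.labels)))
        ids = self.ids or tuple(str(i) for i in range(vecs.shape[0]))
        object.__setattr__(self, "ids", tuple(map(str, ids)))
        if vecs.shape[0] != len(self.labels) or vecs.shape[0] != len(self.ids):
            raise ValueError("vectors, labels and ids must have equal length")
        if vecs.shape[0] < 1:
            raise ValueError("need at least one labeled vector")


@dataclass(frozen=True)
class AccuracyReport:
    """Per-class and overall correct-classification counts."""

    per_class: dict[str, dict]
    total: int
    correct: int
    protocol: str  # "leave-one-out" | "include-self"
    classes_with_single_member: tuple[str, ...] = ()

    @property
    def accuracy(self) -> float:
        return self.correct / self.total

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "classes": [
                {"class": name, **stats} for name, stats in self.per_class.items()
            ],
            "overall": {
                "total": self.total,
                "correct": self.correct,
                "accuracy": self.accuracy,
            },
            "classes_with_single_member": list(self.classes_with_single_member),
        }


class NearestNeighborFamilyClassifier(BaseEstimator, ClassifierMixin):
    """k-nearest-neighbor classifier with the tie rules used throughout.

    Distance ties are broken toward the smallest training index; vote ties
    (k > 1) toward the class appearing earlier in sorted class order.
    Implemented as an exhaustive distance scan — training sets here are
    family-sized, and the deterministic tie behavior is part of the
    contract.

    Parameters
    ----------
    k : int, default 1
        Number of neighbors; 1 is the default protocol throughout.
    """

    def __init__(self, k: int = 1):
        self.k = k

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray([str(v) for v in y], dtype=object)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        if not 1 <= self.k <= X.shape[0]:
            raise ValueError(f"k={self.k} out of range for n={X.shape[0]}")
        self.X_ = X
        self.y_ = y
        self.classes_ = np.unique(y)
        self._class_rank = {c: i for i, c in enumerate(self.classes_)}
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        dist = cdist(X, self.X_)
        return self._decide(dist)

    def _decide(self, dist: np.ndarray) -> np.ndarray:
        """Labels from a (n_queries, n_train) distance matrix.

        Rows may contain +inf to exclude training vectors (self-exclusion).
        """
        if self.k == 1:
            # argmin returns the first minimum -> smallest-index tie rule
            return self.y_[np.argmin(dist, axis=1)]
        out = np.empty(dist.shape[0], dtype=object)
        for q in range(dist.shape[0]):
            order = np.argsort(dist[q], kind="stable")[: self.k]
            votes: dict[str, int] = {}
            for i in order:
                votes[self.y_[i]] = votes.get(self.y_[i], 0) + 1
            best = max(votes.items(), key=lambda kv: (kv[1], -self._class_rank[kv[0]]))
            out[q] = best[0]
        return out


def nearest_neighbor(
    query: np.ndarray,
    train: LabeledVectors,
    exclude_id: str | None = None,
    k: int = 1,
) -> str:
    """Class of the training vector nearest to ``query`` (Euclidean).

    ``exclude_id`` removes one training vector (by id) before the scan, the
    building block of leave-one-out evaluation.
    """
    keep = np.ones(train.vectors.shape[0], dtype=bool)
    if exclude_id is not None:
        keep &= np.asarray([i != exclude_id for i in train.ids])
    if not keep.any():
        raise ValueError("training set is empty after exclusion")
    clf = NearestNeighborFamilyClassifier(k=k).fit(
        train.vectors[keep], [l for l, m in zip(train.labels, keep) if m]
    )
    return str(clf.predict(np.asarray(query, dtype=float)[None, :])[0])


def leave_one_out_evaluate(
    data: LabeledVectors, k: int = 1, include_self: bool = False
) -> AccuracyReport:
    """Classify every vector against all the others; aggregate per class.

    With ``include_self=True`` the naive shared train/test protocol is used
    instead (each vector may match itself), which trivially yields 100%
    accuracy unless duplicates collide across classes.
    """
    clf = NearestNeighborFamilyClassifier(k=k).fit(data.vectors, data.labels)
    dist = cdist(data.vectors, data.vectors)
    if not include_self:
        np.fill_diagonal(dist, np.inf)
    predicted = clf._decide(dist)

    per_class: dict[str, dict] = {}
    order: list[str] = []
    for label in data.labels:
        if label not in per_class:
            per_class[label] = {"total": 0, "correct": 0}
            order.append(label)
    for truth, pred in zip(data.labels, predicted):
        per_class[truth]["total"] += 1
        per_class[truth]["correct"] += int(pred == truth)
    for stats in per_class.values():
        stats["accuracy"] = stats["correct"] / stats["total"]
    singles = tuple(c for c in order if per_class[c]["total"] < 2)
    return AccuracyReport(
        per_class={c: per_class[c] for c in order},
        total=len(data.labels),
        correct=int(sum(per_class[c]["correct"] for c in order)),
        protocol="include-self" if include_self else "leave-one-out",
        classes_with_single_member=singles,
    )
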