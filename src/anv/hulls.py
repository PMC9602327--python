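r"""Convex-hull disjointness tests and centroid distances between families.

Whether the convex hulls of two point sets :math:`A=\{a_i\}` and
:math:`B=\{b_j\}` intersect is decided without building either hull: the
hulls share a point iff the linear program

.. math::

   \sum_i \lambda_i a_i = \sum_j \mu_j b_j,\quad
   \sum_i \lambda_i = 1,\ \sum_j \mu_j = 1,\quad
   \lambda_i, \mu_j \ge 0

is feasible. This stays tractable in 250 dimensions where explicit facet
enumeration is hopeless. Because ANV coordinates span orders of magnitude
(counts vs. covariances), both point sets are jointly centered and scaled to
unit max-absolute-value per dimension before the solve; hull intersection is
invariant under such shared affine maps, so the verdict is unchanged while
the LP becomes well conditioned.

The distance between two families is the Euclidean distance between their
hull centroids (the arithmetic means of the point sets).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

__all__ = [
    "FamilyPointSet",
    "HullPairResult",
    "DistanceMatrix",
    "IndeterminateHullError",
    "hulls_intersect",
    "all_pairs_intersection",
    "hull_centroid",
    "hull_distance",
    "centroid_distance_matrix",
]


@dataclass(frozen=True)
class FamilyPointSet:
    """A labeled family of points (rows) in a shared k-dimensional space."""

    label: str
    points: np.ndarray
    ids: tuple[str, ...] = ()

    def __post_init__(self):
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.shape[0] < 1:
            raise ValueError(f"family {self.label!r} has no points")
        if not np.all(np.isfinite(pts)):
            raise ValueError(f"family {self.label!r} contains non-finite entries")
        object.__setattr__(self, "points", pts)
        if self.ids and len(self.ids) != pts.shape[0]:
            raise ValueError("ids length does not match point count")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def dimension(self) -> int:
        return self.points.shape[1]

    @classmethod
    def from_frame(cls, label: str, frame: pd.DataFrame) -> "FamilyPointSet":
        return cls(label=label, points=frame.to_numpy(dtype=float),
                   ids=tuple(map(str, frame.index)))


@dataclass(frozen=True)
class HullPairResult:
    """Verdict and LP diagnostics for one family pair."""

    label_a: str
    label_b: str
    verdict: str  # "intersect" | "disjoint"
    lp_status: int
    tolerance_used: float
    witness: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)


class IndeterminateHullError(RuntimeError):
    """The LP solver neither found a feasible point nor proved infeasibility.

    Raised instead of guessing a verdict; carries the solver status so the
    caller can count borderline pairs separately.
    """

    def __init__(self, label_a: str, label_b: str, lp_status: int, message: str):
        self.label_a, self.label_b = label_a, label_b
        self.lp_status = lp_status
        super().__init__(
            f"hull test {label_a!r} vs {label_b!r} indeterminate "
            f"(lp_status={lp_status}): {message}"
        )


def _condition(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Jointly center the union and scale each dimension to unit max-abs.

    Dimensions with zero range across the union carry no constraint (both
    centroids match there trivially) and are dropped from the equality block.
    """
    union = np.vstack([a, b])
    center = union.mean(axis=0)
    a, b = a - center, b - center
    span = np.abs(np.vstack([a, b])).max(axis=0)
    keep = span > 0
    a, b = a[:, keep], b[:, keep]
    return a / span[keep], b / span[keep]


def hulls_intersect(
    set_a: FamilyPointSet, set_b: FamilyPointSet, tolerance: float = 1e-8
) -> HullPairResult:
    """LP feasibility test: do the convex hulls of two point sets intersect?

    Returns a :class:`HullPairResult` whose verdict is ``"intersect"`` (the
    solver found convex combinations of the two sets that coincide within
    ``tolerance`` on the conditioned coordinates) or ``"disjoint"`` (the LP
    is proven infeasible). A solver failure raises
    :class:`IndeterminateHullError` rather than guessing.
    """
    if set_a.dimension != set_b.dimension:
        raise ValueError(
            f"dimension mismatch: {set_a.label!r} has k={set_a.dimension}, "
            f"{set_b.label!r} has k={set_b.dimension}"
        )
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")

    a, b = _condition(set_a.points, set_b.points)
    n, m = a.shape[0], b.shape[0]
    k = a.shape[1]

    # variables x = (lambda_1..n, mu_1..m)
    a_eq = np.zeros((k + 2, n + m))
    a_eq[:k, :n] = a.T
    a_eq[:k, n:] = -b.T
    a_eq[k, :n] = 1.0
    a_eq[k + 1, n:] = 1.0
    b_eq = np.zeros(k + 2)
    b_eq[k] = 1.0
    b_eq[k + 1] = 1.0

    res = linprog(
        c=np.zeros(n + m),
        A_eq=a_eq,
        b_eq=b_eq,
        bounds=(0.0, 1.0),
        method="highs",
        options={
            "primal_feasibility_tolerance": min(tolerance, 1e-7),
            "dual_feasibility_tolerance": min(tolerance, 1e-7),
        },
    )

    if res.status == 0:
        lam = np.asarray(res.x[:n])
        mu = np.asarray(res.x[n:])
        return HullPairResult(
            label_a=set_a.label,
            label_b=set_b.label,
            verdict="intersect",
            lp_status=res.status,
            tolerance_used=tolerance,
            witness=(lam, mu),
        )
    if res.status == 2:  # proven infeasible
        return HullPairResult(
            label_a=set_a.label,
            label_b=set_b.label,
            verdict="disjoint",
            lp_status=res.status,
            tolerance_used=tolerance,
        )
    raise IndeterminateHullError(set_a.label, set_b.label, res.status, res.message)


def all_pairs_intersection(
    families: list[FamilyPointSet],
    tolerance: float = 1e-8,
    groups: dict[str, str] | None = None,
) -> tuple[list[HullPairResult], dict]:
    """Hull test over all unordered family pairs, with a summary.

    Parameters
    ----------
    groups:
        Optional family-label -> group-name mapping (e.g. Baltimore class);
        when given, only pairs within the same group are tested.

    Returns
    -------
    results, summary:
        Pair results plus a summary dict with ``pairs_total``, ``disjoint``,
        ``intersecting``, ``indeterminate`` counts and ``disjoint_fraction``
        (over the determinate pairs).
    """
    if len(families) < 2:
        raise ValueError("need at least two families")
    results: list[HullPairResult] = []
    indeterminate = 0
    for fa, fb in itertools.combinations(families, 2):
        if groups is not None and groups.get(fa.label) != groups.get(fb.label):
            continue
        try:
            results.append(hulls_intersect(fa, fb, tolerance))
        except IndeterminateHullError:
            indeterminate += 1
    n_disjoint = sum(r.verdict == "disjoint" for r in results)
    n_intersect = sum(r.verdict == "intersect" for r in results)
    total = n_disjoint + n_intersect + indeterminate
    summary = {
        "pairs_total": total,
        "disjoint": n_disjoint,
        "intersecting": n_intersect,
        "indeterminate": indeterminate,
        "disjoint_fraction": (n_disjoint / (n_disjoint + n_intersect))
        if (n_disjoint + n_intersect)
        else float("nan"),
    }
    return results, summary


def hull_centroid(set_a: FamilyPointSet) -> np.ndarray:
    """Centroid (coordinate-wise mean) of a family's point set."""
    return set_a.points.mean(axis=0)


def hull_distance(set_a: FamilyPointSet, set_b: FamilyPointSet) -> float:
    """Euclidean distance between the two family centroids."""
    if set_a.dimension != set_b.dimension:
        raise ValueError("dimension mismatch between families")
    return float(np.linalg.norm(hull_centroid(set_a) - hull_centroid(set_b)))


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative distance matrix over labeled items."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        if not np.all(np.isfinite(vals)):
            raise ValueError("distance matrix has non-finite entries")
        if np.abs(vals - vals.T).max(initial=0.0) > 1e-9:
            raise ValueError("distance matrix is not symmetric within 1e-9")
        if np.any(vals < 0):
            raise ValueError("distance matrix has negative entries")
        vals = (vals + vals.T) / 2.0
        np.fill_diagonal(vals, 0.0)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "labels", tuple(self.labels))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels),
                            columns=list(self.labels))


def centroid_distance_matrix(families: list[FamilyPointSet]) -> DistanceMatrix:
    """Pairwise hull-centroid distance matrix over a list of families."""
    if len(families) < 2:
        raise ValueError("need at least two families")
    dims = {f.dimension for f in families}
    if len(dims) > 1:
        raise ValueError(f"families have mixed dimensions: {sorted(dims)}")
    centroids = np.vstack([hull_centroid(f) for f in families])
    diff = centroids[:, None, :] - centroids[None, :, :]
    values = np.sqrt((diff**2).sum(axis=2))
    return DistanceMatrix(labels=tuple(f.label for f in families), values=values)
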