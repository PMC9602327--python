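r"""Two-class supervised projection to 1–2 dimensions: LDA and MMC.

Linear discriminant analysis seeks the direction :math:`\omega` maximizing
the Rayleigh quotient :math:`J(\omega)=\omega^T S_b \omega / \omega^T S_w
\omega`, solved by the top eigenvectors of :math:`S_w^{-1} S_b`, where
:math:`S_w = \Sigma_0 + \Sigma_1` is the within-class scatter and
:math:`S_b = (\mu_0-\mu_1)(\mu_0-\mu_1)^T` the between-class scatter. With
fewer samples than dimensions :math:`S_w` is singular (the small-sample-size
problem) and LDA is undefined; the maximum margin criterion sidesteps the
inverse by maximizing :math:`\mathrm{tr}\,\omega^T(S_b-S_w)\omega` over
orthonormal :math:`\omega`, i.e. the top eigenvectors of the symmetric
matrix :math:`S_b - S_w`.

For two classes :math:`S_b` has rank one, so only the leading direction is
determined by either criterion; a requested second direction is the
next eigenvector of the same matrix, and the result flags the degeneracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, TransformerMixin

from .hulls import FamilyPointSet

__all__ = [
    "TwoClassSample",
    "ProjectionResult",
    "SmallSampleSizeError",
    "scatter_matrices",
    "lda_project",
    "mmc_project",
    "LinearDiscriminantProjector",
    "MaxMarginProjector",
]

#: Reject LDA when cond(Sw) exceeds this (effectively singular).
_SW_CONDITION_LIMIT = 1e12


class SmallSampleSizeError(np.linalg.LinAlgError):
    """Within-class scatter is singular, so LDA is undefined.

    Typically the sample count is at most the dimension (n0 + n1 <= D).
    The maximum margin criterion (``mmc_project`` /
    :class:`MaxMarginProjector`) avoids the inverse and is the remedy.
    """


@dataclass(frozen=True)
class TwoClassSample:
    """Two labeled point sets sharing a dimension (classes j = 0, 1)."""

    class0: FamilyPointSet
    class1: FamilyPointSet

    def __post_init__(self):
        if self.class0.dimension != self.class1.dimension:
            raise ValueError("the two classes must share a dimension")

    @property
    def dimension(self) -> int:
        return self.class0.dimension


@dataclass(frozen=True)
class ProjectionResult:
    """Projection basis, spectrum and the two projected point sets."""

    basis: np.ndarray  # D x d, columns are directions
    eigenvalues: np.ndarray  # length d, non-increasing
    projected0: np.ndarray
    projected1: np.ndarray
    method: str  # "lda" | "mmc"
    rank_deficient: bool  # second direction not determined by the criterion


def scatter_matrices(sample: TwoClassSample) -> tuple[np.ndarray, np.ndarray]:
    """Within-class (Sw) and between-class (Sb) scatter matrices.

    ``Sw`` is the sum of the two classes' (uncentered-by-count) scatter
    sums; ``Sb`` is the rank-one outer product of the class-mean difference.
    """
    sw = np.zeros((sample.dimension, sample.dimension))
    means = []
    for cls in (sample.class0, sample.class1):
        mu = cls.points.mean(axis=0)
        centered = cls.points - mu
        sw += centered.T @ centered
        means.append(mu)
    dmu = means[0] - means[1]
    sb = np.outer(dmu, dmu)
    return sw, sb


def _fix_signs(basis: np.ndarray) -> np.ndarray:
    # Deterministic orientation: largest-magnitude component positive.
    for col in range(basis.shape[1]):
        i = int(np.argmax(np.abs(basis[:, col])))
        if basis[i, col] < 0:
            basis[:, col] = -basis[:, col]
    return basis


def _project(sample: TwoClassSample, basis: np.ndarray):
    return sample.class0.points @ basis, sample.class1.points @ basis


def lda_project(sample: TwoClassSample, d: int = 2) -> ProjectionResult:
    """Two-class LDA projection onto the top ``d`` discriminant directions.

    Solves the generalized symmetric eigenproblem ``Sb v = lambda Sw v``
    (equivalent to eigenvectors of ``Sw^{-1} Sb``); directions are
    unit-normalized with a deterministic sign. Raises
    :class:`SmallSampleSizeError` when ``Sw`` is numerically singular.
    """
    if d not in (1, 2):
        raise ValueError("d must be 1 or 2")
    sw, sb = scatter_matrices(sample)
    if np.linalg.cond(sw) > _SW_CONDITION_LIMIT:
        raise SmallSampleSizeError(
            "within-class scatter matrix is singular or near-singular "
            f"(condition number exceeds {_SW_CONDITION_LIMIT:g}); this is the "
            "small sample size problem — use the maximum margin criterion "
            "(mmc_project) instead"
        )
    eigvals, eigvecs = scipy.linalg.eigh(sb, sw)
    order = np.argsort(eigvals)[::-1][:d]
    vals = eigvals[order]
    basis = eigvecs[:, order]
    basis = basis / np.linalg.norm(basis, axis=0, keepdims=True)
    basis = _fix_signs(basis)
    p0, p1 = _project(sample, basis)
    return ProjectionResult(
        basis=basis,
        eigenvalues=vals,
        projected0=p0,
        projected1=p1,
        method="lda",
        rank_deficient=d > 1,
    )


def mmc_project(sample: TwoClassSample, d: int = 2) -> ProjectionResult:
    """Maximum-margin-criterion projection onto ``d`` orthonormal directions.

    Takes the top eigenvectors of the symmetric matrix ``Sb - Sw``; never
    requires inverting ``Sw``, so it works when samples are scarcer than
    dimensions.
    """
    if d not in (1, 2):
        raise ValueError("d must be 1 or 2")
    sw, sb = scatter_matrices(sample)
    eigvals, eigvecs = scipy.linalg.eigh(sb - sw)
    order = np.argsort(eigvals)[::-1][:d]
    basis = _fix_signs(eigvecs[:, order].copy())
    p0, p1 = _project(sample, basis)
    return ProjectionResult(
        basis=basis,
        eigenvalues=eigvals[order],
        projected0=p0,
        projected1=p1,
        method="mmc",
        rank_deficient=d > 1,
    )


class _TwoClassProjectorBase(BaseEstimator, TransformerMixin):
    """Shared fit/transform plumbing for the two-class projectors."""

    _method: str

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.shape[0] != 2:
            raise ValueError(
                f"{type(self).__name__} is a two-class method; got "
                f"{classes.shape[0]} classes"
            )
        self.classes_ = classes
        sample = TwoClassSample(
            class0=FamilyPointSet(str(classes[0]), X[y == classes[0]]),
            class1=FamilyPointSet(str(classes[1]), X[y == classes[1]]),
        )
        result = self._solve(sample, self.n_components)
        self.components_ = result.basis.T  # sklearn convention: (d, D)
        self.eigenvalues_ = result.eigenvalues
        self.rank_deficient_ = result.rank_deficient
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return X @ self.components_.T

    def _solve(self, sample: TwoClassSample, d: int) -> ProjectionResult:
        raise NotImplementedError


class LinearDiscriminantProjector(_TwoClassProjectorBase):
    """sklearn-style two-class LDA projector (see :func:`lda_project`)."""

    _method = "lda"

    def _solve(self, sample, d):
        return lda_project(sample, d)


class MaxMarginProjector(_TwoClassProjectorBase):
    """sklearn-style MMC projector (see :func:`mmc_project`); robust to
    n < D, where plain LDA fails."""

    _method = "mmc"

    def _solve(self, sample, d):
        return mmc_project(sample, d)
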