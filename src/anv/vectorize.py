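r"""The accumulated natural vector (ANV) of a protein sequence.

A sequence :math:`S = (s_1,\dots,s_N)` over the 20-letter amino-acid alphabet
is summarized by the *accumulated indicator functions*

.. math:: \tilde I_\alpha(k) = \#\{i \le k : s_i = \alpha\},

the running occurrence counts of each residue. From these curves the ANV
collects, for every residue :math:`\alpha`,

* the count :math:`n_\alpha = \tilde I_\alpha(N)`,
* the mean position :math:`\zeta_\alpha = \sum_k \tilde I_\alpha(k) / n_\alpha`,
* the variance :math:`D_\alpha = \sum_k (\tilde I_\alpha(k)-\theta_\alpha)^2 / n_\alpha^2`,

and for every ordered residue pair :math:`(\alpha,\beta)` the covariance

.. math::

   \mathrm{cov}(\alpha,\beta) =
   \frac{\sum_k (\tilde I_\alpha(k)-\theta_\alpha)
                (\tilde I_\beta(k)-\theta_\beta)}{n_\alpha n_\beta},
   \qquad \theta_\alpha = \frac{1}{N}\sum_k \tilde I_\alpha(k).

The four blocks — 20 counts, 20 mean positions, 20 variances, 190 covariances
in lexicographic pair order — form a fixed 250-dimensional embedding; the
Euclidean distance between two embeddings serves as an alignment-free
dissimilarity between the sequences. Residues absent from the sequence
contribute zeros (mean position, variance and every covariance involving
them are defined as 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .alphabet import (
    AMINO_ACIDS,
    ANV_COLUMNS,
    ANV_DIMENSION,
    N_RESIDUES,
    PAIR_INDICES,
    RESIDUE_INDEX,
)
from .sequences import ProteinSequence, encode, make_sequence

logger = logging.getLogger(__name__)

__all__ = [
    "AccumulatedIndicatorTable",
    "accumulate_indicators",
    "count_residues",
    "mean_positions",
    "covariance",
    "variance",
    "build_anv",
    "vectorize_collection",
    "ANVVectorizer",
]


@dataclass(frozen=True)
class AccumulatedIndicatorTable:
    """20 x N table; row alpha, column k holds the running count of alpha
    among sequence positions 1..k (columns are 1-based positions)."""

    values: np.ndarray
    sequence_length: int

    def row(self, residue: str) -> np.ndarray:
        return self.values[RESIDUE_INDEX[residue]]


def accumulate_indicators(seq: ProteinSequence) -> AccumulatedIndicatorTable:
    """Accumulated indicator curves of all 20 residues for one sequence."""
    idx = encode(seq)
    n = len(seq)
    indicators = np.zeros((N_RESIDUES, n), dtype=np.int64)
    indicators[idx, np.arange(n)] = 1
    table = np.cumsum(indicators, axis=1)
    return AccumulatedIndicatorTable(values=table, sequence_length=n)


def count_residues(table: AccumulatedIndicatorTable) -> np.ndarray:
    """Residue counts n_alpha — the last column of the accumulated table."""
    return table.values[:, -1].copy()


def _theta(table: AccumulatedIndicatorTable) -> np.ndarray:
    # theta_alpha = (sum_k Itilde_alpha(k)) / N  — the centering constant of
    # the covariance, not the mean position.
    return table.values.sum(axis=1) / table.sequence_length


def mean_positions(table: AccumulatedIndicatorTable) -> np.ndarray:
    """Mean positions zeta_alpha; 0 for residues absent from the sequence."""
    counts = count_residues(table)
    sums = table.values.sum(axis=1)
    out = np.zeros(N_RESIDUES)
    present = counts > 0
    out[present] = sums[present] / counts[present]
    return out


def covariance(table: AccumulatedIndicatorTable, alpha: str, beta: str) -> float:
    """Covariance of the accumulated curves of two residues (symmetric);
    0 if either residue is absent. ``alpha == beta`` gives the variance."""
    i, j = RESIDUE_INDEX[alpha], RESIDUE_INDEX[beta]
    counts = count_residues(table)
    if counts[i] == 0 or counts[j] == 0:
        return 0.0
    theta = _theta(table)
    dev = table.values.astype(float) - theta[:, None]
    return float(dev[i] @ dev[j] / (counts[i] * counts[j]))


def variance(table: AccumulatedIndicatorTable, alpha: str) -> float:
    """Variance D_alpha = cov(alpha, alpha); 0 for an absent residue."""
    return covariance(table, alpha, alpha)


def build_anv(seq: ProteinSequence) -> np.ndarray:
    """The 250-dimensional accumulated natural vector of one sequence.

    Layout: ``(n_A..n_V, zeta_A..zeta_V, D_A..D_V, cov_A_R..cov_Y_V)`` with
    the covariance block in lexicographic pair order over the fixed alphabet.
    """
    table = accumulate_indicators(seq)
    counts = count_residues(table).astype(float)
    zeta = mean_positions(table)

    theta = _theta(table)
    dev = table.values.astype(float) - theta[:, None]
    cross = dev @ dev.T  # 20x20 matrix of summed deviation products
    with np.errstate(divide="ignore", invalid="ignore"):
        covmat = cross / np.outer(counts, counts)
    absent = counts == 0
    covmat[absent, :] = 0.0
    covmat[:, absent] = 0.0

    variances = np.diag(covmat)
    cov_block = covmat[PAIR_INDICES[:, 0], PAIR_INDICES[:, 1]]
    vec = np.concatenate([counts, zeta, variances, cov_block])
    assert vec.shape == (ANV_DIMENSION,)
    return vec


def vectorize_collection(
    seqs: list[ProteinSequence], *, policy_applied: bool = True
) -> pd.DataFrame:
    """ANVs for a collection of sequences as a DataFrame.

    One row per sequence in input order; the index carries the sequence ids.
    Duplicate ids are disambiguated with a numeric suffix and logged.
    """
    if not seqs:
        raise ValueError("vectorize_collection requires at least one sequence")
    ids = []
    seen: dict[str, int] = {}
    for s in seqs:
        sid = s.id
        if sid in seen:
            seen[sid] += 1
            new_id = f"{sid}__{seen[sid]}"
            logger.warning("duplicate sequence id %r renamed to %r", sid, new_id)
            sid = new_id
        else:
            seen[sid] = 0
        ids.append(sid)
    mat = np.vstack([build_anv(s) for s in seqs])
    return pd.DataFrame(mat, index=pd.Index(ids, name="id"), columns=list(ANV_COLUMNS))


class ANVVectorizer(BaseEstimator, TransformerMixin):
    """Stateless sklearn transformer: protein sequences -> 250-D ANV matrix.

    Accepts raw residue strings, ``(id, residues)`` pairs, or
    :class:`~anv.sequences.ProteinSequence` objects.

    Parameters
    ----------
    policy:
        Residue sanitization policy for raw strings, ``"strict"`` (reject
        non-canonical residues) or ``"drop"`` (delete them, with a warning).

    Examples
    --------
    >>> ANVVectorizer().fit_transform(["ARRNADCDCC"]).shape
    (1, 250)
    """

    def __init__(self, policy: str = "strict"):
        self.policy = policy

    def fit(self, X, y=None):
        self._coerce(X[:1] if len(X) else X)  # validate policy eagerly
        self.n_features_in_ = None  # sequences, not a feature matrix
        return self

    def transform(self, X) -> np.ndarray:
        seqs = self._coerce(X)
        if not seqs:
            raise ValueError("empty sequence collection")
        return np.vstack([build_anv(s) for s in seqs])

    def get_feature_names_out(self, input_features=None):
        return np.asarray(ANV_COLUMNS, dtype=object)

    def _coerce(self, X) -> list[ProteinSequence]:
        out = []
        for k, item in enumerate(X):
            if isinstance(item, ProteinSequence):
                out.append(item)
            elif isinstance(item, str):
                out.append(make_sequence(f"seq{k}", item, policy=self.policy))
            else:
                sid, residues = item
                out.append(make_sequence(sid, residues, policy=self.policy))
        return out
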