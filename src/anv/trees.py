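"""Distance-based grouping of families: single-linkage clusters and NJ trees.

Families are summarized by their hull centroids; the centroid distance
matrix feeds either single-linkage ("shortest distance") agglomeration cut
at a requested cluster count, or Saitou–Nei neighbor joining for an unrooted
tree with branch lengths, serialized as Newick. NJ is exact on additive
matrices, which is what the test oracle exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix as _SkbioDM
from skbio import TreeNode
from skbio.tree import nj as _skbio_nj

from .hulls import DistanceMatrix, FamilyPointSet, centroid_distance_matrix

__all__ = [
    "LinkageResult",
    "PhyloTree",
    "single_linkage",
    "neighbor_joining",
    "cluster_report",
]


@dataclass(frozen=True)
class LinkageResult:
    """Single-linkage merge history plus a flat cut at k clusters."""

    merges: np.ndarray  # scipy linkage matrix, rows (a, b, height, size)
    assignment: dict[str, int]  # label -> cluster index, 0..k-1
    k: int

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def single_linkage(dist: DistanceMatrix, k: int) -> LinkageResult:
    """Agglomerate by minimum inter-cluster distance; cut into k clusters.

    Cluster indices are renumbered 0..k-1 by first appearance in label
    order, so the assignment is stable across runs.
    """
    n = len(dist.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} labels")
    if n == 1:
        return LinkageResult(
            merges=np.empty((0, 4)), assignment={dist.labels[0]: 0}, k=1
        )
    merges = sch.linkage(squareform(dist.values, checks=False), method="single")
    raw = sch.fcluster(merges, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    assignment = {}
    for label, c in zip(dist.labels, raw):
        if c not in remap:
            remap[c] = len(remap)
        assignment[label] = remap[c]
    return LinkageResult(merges=merges, assignment=assignment, k=len(remap))


@dataclass(frozen=True)
class PhyloTree:
    """Unrooted tree over the family labels with branch lengths >= 0."""

    tree: TreeNode

    @property
    def leaf_names(self) -> frozenset[str]:
        return frozenset(t.name for t in self.tree.tips())

    def total_branch_length(self) -> float:
        return float(
            sum(n.length or 0.0 for n in self.tree.traverse(include_self=False))
        )

    def to_newick(self) -> str:
        return str(self.tree).strip()

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        return cls(tree=TreeNode.read([newick]))


def neighbor_joining(dist: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining on a family distance matrix.

    Negative branch lengths produced on non-additive inputs are clamped to
    zero. Requires at least three labels.
    """
    if len(dist.labels) < 3:
        raise ValueError("neighbor joining requires at least 3 labels")
    dm = _SkbioDM(dist.values, ids=list(dist.labels))
    tree = _skbio_nj(dm, neg_as_zero=True)
    return PhyloTree(tree=tree)


def cluster_report(
    families: list[FamilyPointSet], k: int, project_2d: bool = False
) -> pd.DataFrame:
    """Flat single-linkage clustering of family centroids.

    Returns a DataFrame indexed by family label with a ``cluster`` column;
    with ``project_2d`` the centroids' top-2 principal-component coordinates
    are added as ``x``/``y`` (a visualization aid only — the axes are the
    centroid cloud's PCA, not a supervised projection).
    """
    if len(families) < k:
        raise ValueError(f"need at least k={k} families, got {len(families)}")
    dist = centroid_distance_matrix(families)
    linkage = single_linkage(dist, k)
    frame = pd.DataFrame(
        {"cluster": [linkage.assignment[f.label] for f in families]},
        index=pd.Index([f.label for f in families], name="family"),
    )
    if project_2d:
        centroids = np.vstack([f.points.mean(axis=0) for f in families])
        centered = centroids - centroids.mean(axis=0)
        # top-2 principal directions via SVD; deterministic sign
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        basis = vt[:2].T if vt.shape[0] >= 2 else np.pad(vt.T, ((0, 0), (0, 1)))
        for col in range(basis.shape[1]):
            i = int(np.argmax(np.abs(basis[:, col])))
            if basis[i, col] < 0:
                basis[:, col] = -basis[:, col]
        coords = centered @ basis
        frame["x"] = coords[:, 0]
        frame["y"] = coords[:, 1]
    return frame
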