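"""File formats: FASTA input, vector tables, distance matrices, Newick.

TSV (tab-separated, UTF-8, Unix newlines, '.' decimal) is the canonical
tabular dialect. Numeric values are written with 12 significant digits so
that downstream LP feasibility tests are not perturbed by rounding.
A PHYLIP square matrix writer/reader is provided for interchange with
phylogenetics tools.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .alphabet import ANV_COLUMNS
from .hulls import DistanceMatrix, FamilyPointSet
from .sequences import ProteinSequence, make_sequence
from .trees import PhyloTree

logger = logging.getLogger(__name__)

__all__ = [
    "read_fasta",
    "write_vectors",
    "read_vectors",
    "point_sets_from_table",
    "write_distance_matrix",
    "read_distance_matrix",
    "write_phylip",
    "read_phylip",
    "write_newick",
    "read_newick",
]

_FLOAT_FORMAT = "%.12g"


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "r")


def read_fasta(path: str | Path, policy: str = "strict") -> list[ProteinSequence]:
    """Parse a FASTA file (plain or gzip) into validated protein sequences.

    Record ids are the first whitespace-delimited token of each header, in
    file order. Lowercase residues are uppercased; non-canonical residues
    are handled per ``policy`` (see :func:`anv.sequences.make_sequence`).
    """
    with _open_text(path) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        residues = str(rec.seq)
        if not residues:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        if residues != residues.upper():
            logger.info("%s: record %r uppercased", path, rec.id)
        out.append(make_sequence(rec.id, residues, policy=policy))
    return out


def write_vectors(table: pd.DataFrame, path: str | Path) -> None:
    """Write an ANV table (index = id, 250 named columns) as TSV."""
    table.to_csv(path, sep="\t", float_format=_FLOAT_FORMAT, index_label="id",
                 lineterminator="\n")


def read_vectors(path: str | Path) -> pd.DataFrame:
    """Read an ANV table written by :func:`write_vectors`.

    Extra columns (e.g. a family column) are preserved; the 250 vector
    columns must all be present.
    """
    frame = pd.read_csv(path, sep="\t", index_col="id")
    missing = [c for c in ANV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(
            f"{path}: not a vector table — missing {len(missing)} vector "
            f"columns (first: {missing[0]!r})"
        )
    return frame


def point_sets_from_table(
    frame: pd.DataFrame, family_col: str = "family"
) -> list[FamilyPointSet]:
    """Split a vector table with a family column into labeled point sets.

    Families appear in first-occurrence order; only the 250 vector columns
    enter the point sets.
    """
    if family_col not in frame.columns:
        raise ValueError(f"table has no {family_col!r} column")
    sets = []
    for label in frame[family_col].drop_duplicates():
        sub = frame.loc[frame[family_col] == label, list(ANV_COLUMNS)]
        sets.append(FamilyPointSet.from_frame(str(label), sub))
    return sets


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    """Square labeled distance matrix as TSV."""
    dm.to_frame().to_csv(path, sep="\t", float_format=_FLOAT_FORMAT,
                         index_label="", lineterminator="\n")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if list(frame.index) != list(frame.columns):
        raise ValueError(f"{path}: row and column labels differ")
    return DistanceMatrix(labels=tuple(map(str, frame.index)),
                          values=frame.to_numpy(dtype=float))


def write_phylip(dm: DistanceMatrix, path: str | Path) -> None:
    """PHYLIP square distance matrix (relaxed: full labels, tab-separated)."""
    with open(path, "w", newline="\n") as fh:
        fh.write(f"{len(dm.labels)}\n")
        for label, row in zip(dm.labels, dm.values):
            fh.write(label + "\t" + "\t".join(_FLOAT_FORMAT % v for v in row) + "\n")


def read_phylip(path: str | Path) -> DistanceMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    n = int(lines[0].split()[0])
    if len(lines) != n + 1:
        raise ValueError(f"{path}: expected {n} matrix rows, found {len(lines) - 1}")
    labels, rows = [], []
    for ln in lines[1:]:
        parts = ln.split()
        labels.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    values = np.asarray(rows, dtype=float)
    if values.shape != (n, n):
        raise ValueError(f"{path}: matrix is not {n}x{n}")
    return DistanceMatrix(labels=tuple(labels), values=values)


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(tree.to_newick() + "\n")


def read_newick(path: str | Path) -> PhyloTree:
    with open(path) as fh:
        return PhyloTree.from_newick(fh.read().strip())
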