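"""Validated protein sequences and the residue-sanitization policies."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .alphabet import AMINO_ACIDS, RESIDUE_INDEX

logger = logging.getLogger(__name__)

_ALPHABET_SET = frozenset(AMINO_ACIDS)

POLICIES = ("strict", "drop")


class InvalidResidueError(ValueError):
    """A sequence contains a character outside the 20-letter alphabet."""

    def __init__(self, seq_id: str, char: str, position: int):
        self.seq_id = seq_id
        self.char = char
        self.position = position  # 1-based
        super().__init__(
            f"sequence {seq_id!r}: invalid residue {char!r} at position "
            f"{position} (strict policy rejects non-canonical characters)"
        )


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence over the canonical 20-letter alphabet.

    Construct via :func:`make_sequence` to apply a sanitization policy;
    direct construction validates strictly.
    """

    id: str
    residues: str = field(repr=False)

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in _ALPHABET_SET:
                raise InvalidResidueError(self.id, ch, pos)

    def __len__(self) -> int:
        return len(self.residues)


def make_sequence(seq_id: str, residues: str, policy: str = "strict") -> ProteinSequence:
    """Build a validated :class:`ProteinSequence` under a sanitization policy.

    Parameters
    ----------
    policy:
        ``"strict"`` rejects any character outside the 20 canonical residues,
        naming the offender and its 1-based position. ``"drop"`` deletes
        non-canonical characters before indexing and logs a warning (dropping
        shifts positions, so it is never silent). Lowercase input is
        uppercased under both policies.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown sanitization policy {policy!r}; choose from {POLICIES}")
    residues = residues.upper()
    if policy == "drop":
        kept = [ch for ch in residues if ch in _ALPHABET_SET]
        n_dropped = len(residues) - len(kept)
        if n_dropped:
            logger.warning(
                "sequence %r: dropped %d non-canonical residue(s)", seq_id, n_dropped
            )
        residues = "".join(kept)
        if not residues:
            raise ValueError(
                f"sequence {seq_id!r} has no canonical residues after dropping"
            )
    return ProteinSequence(id=seq_id, residues=residues)


def encode(seq: ProteinSequence):
    """Residue string -> integer index array (0..19), 1 entry per position."""
    import numpy as np

    return np.fromiter(
        (RESIDUE_INDEX[ch] for ch in seq.residues), dtype=np.intp, count=len(seq)
    )
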