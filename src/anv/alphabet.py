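"""The 20-letter amino-acid alphabet and the fixed 250-dimensional vector layout.

The alphabet order is load-bearing: it fixes the position of every component
of the accumulated natural vector (counts, mean positions, variances, and the
190 ordered residue pairs of the covariance block). It must never be changed.
"""

from __future__ import annotations

import numpy as np

#: Canonical residue order. Fixes the ANV layout across the whole package.
AMINO_ACIDS: tuple[str, ...] = (
    "A", "R", "N", "D", "C", "E", "Q", "G", "H", "I",
    "L", "K", "M", "F", "P", "S", "T", "W", "Y", "V",
)

N_RESIDUES = len(AMINO_ACIDS)

#: Residue letter -> row index in every 20-row table.
RESIDUE_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Ordered residue pairs (alpha strictly before beta in alphabet order),
#: lexicographic: (A,R),(A,N),...,(A,V),(R,N),...,(Y,V). 190 pairs.
RESIDUE_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (AMINO_ACIDS[i], AMINO_ACIDS[j])
    for i in range(N_RESIDUES)
    for j in range(i + 1, N_RESIDUES)
)

#: Integer index pairs matching RESIDUE_PAIRS.
PAIR_INDICES: np.ndarray = np.array(
    [(i, j) for i in range(N_RESIDUES) for j in range(i + 1, N_RESIDUES)],
    dtype=np.intp,
)

ANV_DIMENSION = 3 * N_RESIDUES + len(RESIDUE_PAIRS)  # 250

#: Column names of the canonical vector table, in vector order.
ANV_COLUMNS: tuple[str, ...] = (
    tuple(f"n_{a}" for a in AMINO_ACIDS)
    + tuple(f"zeta_{a}" for a in AMINO_ACIDS)
    + tuple(f"D_{a}" for a in AMINO_ACIDS)
    + tuple(f"cov_{a}_{b}" for a, b in RESIDUE_PAIRS)
)

#: Ambiguity codes and other characters rejected under the strict policy.
NON_CANONICAL = frozenset("BZXUOJ*-.")
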