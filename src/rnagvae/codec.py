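"""Binary L x 17 encoding of parse trees.

Columns 1-6 (``Bn``) hold the one-hot character of each position in the
order a, c, g, u, -, x.  Columns 7-17 (``Bg``) hold grammar flags: each
two-index rule type writes a 1 at row ``i`` of its left column and row
``j`` of the following column (``ss``: 7/8, ``st``: 9/10, ``tt``: 11/12,
``tu``: 13/14); the bifurcation ``tb`` writes rows ``i``, ``j``, ``k`` of
columns 15, 16, 17.  The pair rule ``us`` writes no grammar columns — its
information lives entirely in the one-hot characters of the two partners.
Cell collisions between rules are resolved by OR (the matrix stays
binary).  The terminal ``S[i,i] -> n`` is encoded as a degenerate ``ss``
with ``j = i`` (both columns 7 and 8 at row ``i``).
"""

from __future__ import annotations

import numpy as np

from .grammar import (
    CHAR_COLUMN,
    ParseTree,
    ProductionRule,
    SS,
    ST,
    TT,
    TU,
    TB,
    US,
)

#: Total number of columns: 6 nucleotide + 11 grammar.
N_COLUMNS = 17
#: Number of nucleotide (one-hot) columns.
N_NUC = 6
#: Number of grammar columns.
N_GRAMMAR = 11

#: 1-based left column of each two-index rule type.
RULE_COLUMN = {SS: 7, ST: 9, TT: 11, TU: 13}
#: 1-based columns of the three bifurcation indices i, j, k.
TB_COLUMNS = (15, 16, 17)


def encode(t: ParseTree, L: int | None = None) -> np.ndarray:
    """Encode a parse tree as an ``L x 17`` {0,1} matrix.

    Raises ``ValueError`` if the tree's span disagrees with ``L`` or a
    position is never emitted (the one-hot block would be invalid).
    """
    if L is None:
        L = t.length
    if t.length != L:
        raise ValueError(f"tree derives length {t.length}, expected {L}")
    B = np.zeros((L, N_COLUMNS), dtype=np.int8)
    for r in t.rules:
        _write_rule(B, r)
    row_sums = B[:, :N_NUC].sum(axis=1)
    if not np.all(row_sums == 1):
        bad = np.flatnonzero(row_sums != 1) + 1
        raise ValueError(f"rows without a unique character: {bad.tolist()}")
    return B


def _write_rule(B: np.ndarray, r: ProductionRule) -> None:
    i, j = r.i - 1, r.j - 1
    if r.rule_type in RULE_COLUMN:
        t = RULE_COLUMN[r.rule_type] - 1
        B[i, t] = 1
        B[j, t + 1] = 1
        if r.rule_type == SS:
            B[i, CHAR_COLUMN[r.left_char] - 1] = 1
        elif r.rule_type == TT:
            B[j, CHAR_COLUMN[r.right_char] - 1] = 1
    elif r.rule_type == TB:
        ci, cj, ck = (c - 1 for c in TB_COLUMNS)
        B[i, ci] = 1
        B[j, cj] = 1
        B[r.k - 1, ck] = 1
    elif r.rule_type == US:
        B[i, CHAR_COLUMN[r.left_char] - 1] = 1
        B[j, CHAR_COLUMN[r.right_char] - 1] = 1
    else:  # pragma: no cover - rule types are closed
        raise ValueError(f"unknown rule type {r.rule_type}")


def flatten(B: np.ndarray) -> np.ndarray:
    """Row-major concatenation of the matrix into a length ``L*17`` vector
    (the model's input/output contract)."""
    if B.ndim != 2 or B.shape[1] != N_COLUMNS:
        raise ValueError(f"expected an L x {N_COLUMNS} matrix, got {B.shape}")
    return np.asarray(B).reshape(-1)


def unflatten(v: np.ndarray, L: int) -> np.ndarray:
    """Inverse of :func:`flatten`."""
    v = np.asarray(v)
    if v.ndim != 1 or v.size != L * N_COLUMNS:
        raise ValueError(f"vector of size {v.size} is not L*{N_COLUMNS} with L={L}")
    return v.reshape(L, N_COLUMNS)


def to_tsv(B: np.ndarray) -> str:
    """Dense tab-separated dump (debugging aid), one row per position."""
    return "\n".join("\t".join(f"{x:g}" for x in row) for row in np.asarray(B))


def from_tsv(text: str) -> np.ndarray:
    """Parse a matrix written by :func:`to_tsv`."""
    rows = [
        [float(tok) for tok in line.split("\t")]
        for line in text.strip().splitlines()
        if line.strip()
    ]
    B = np.array(rows, dtype=np.float64)
    if B.ndim != 2 or B.shape[1] != N_COLUMNS:
        raise ValueError(f"TSV dump is not L x {N_COLUMNS}")
    return B


def nucleotide_onehot(sequence: str) -> np.ndarray:
    """One-hot ``L x 6`` block of a bare sequence (structure-free baseline
    encoding)."""
    B = np.zeros((len(sequence), N_NUC), dtype=np.int8)
    for pos, ch in enumerate(sequence):
        if ch not in CHAR_COLUMN:
            raise ValueError(f"illegal character {ch!r}")
        B[pos, CHAR_COLUMN[ch] - 1] = 1
    return B
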