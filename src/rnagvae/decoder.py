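"""Maximum-score parse-tree recovery from a reconstructed matrix.

Given a reconstructed matrix ``B_hat`` with entries in [0, 1], every
production rule gets a score ``pi`` equal to the product of the matrix
cells it would have written (plus the one-hot cells of its emitted
characters)::

    pi(ss[i,j,n])     = B[i,7]  * B[j,8]  * B[i,I_n]
    pi(st[i,j])       = B[i,9]  * B[j,10]
    pi(tt[i,j,n])     = B[i,11] * B[j,12] * B[j,I_n]
    pi(tu[i,j])       = B[i,13] * B[j,14]
    pi(tb[i,j,k])     = B[i,15] * B[j,16] * B[k,17]
    pi(us[i,j,n,n'])  = B[i,I_n] * B[j,I_n']

The best complete derivation maximizes the product of its rule scores;
it is found by a CYK-style O(L^3) dynamic program over three L x L
tables ``M_S``, ``M_T``, ``M_U`` followed by a traceback.  Infeasible
spans (``T``/``U`` shorter than 3) carry a distinguished impossible
marker (-1), never score 0, so a zero-score feasible parse still beats
an illegal one.

Ties are broken deterministically: at ``S``, ``ss`` before ``st``; at
``T``, ``tt`` before ``tu`` before ``tb`` with splits in increasing
``k``; characters in alphabet order; pairs in the canonical order
au, ua, cg, gc, gu, ug.  The first maximum wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codec import N_COLUMNS
from .grammar import (
    ALPHABET,
    CANONICAL_PAIRS,
    CHAR_COLUMN,
    ParseTree,
    ProductionRule,
    RnaInput,
    SS,
    ST,
    TT,
    TU,
    TB,
    US,
    enumerate_tree_shapes,
    realize,
)

#: Marker for infeasible DP cells; real scores live in [0, 1].
IMPOSSIBLE = -1.0

_PAIR_COLS = [(CHAR_COLUMN[p[0]] - 1, CHAR_COLUMN[p[1]] - 1) for p in CANONICAL_PAIRS]


@dataclass
class DecodedResult:
    """A decoded parse tree, its realized record and its score."""

    tree: ParseTree
    rna: RnaInput
    score: float


def _check_matrix(B: np.ndarray) -> np.ndarray:
    B = np.asarray(B, dtype=np.float64)
    if B.ndim != 2 or B.shape[1] != N_COLUMNS:
        raise ValueError(f"expected L x {N_COLUMNS}, got {B.shape}")
    if B.min() < -1e-9 or B.max() > 1 + 1e-9:
        raise ValueError("matrix entries must lie in [0, 1]")
    return np.clip(B, 0.0, 1.0)


def rule_score(B: np.ndarray, r: ProductionRule) -> float:
    """Score ``pi`` of a single production rule under ``B``.

    For ``ss``/``tt``/``us`` without recorded characters the best
    character (first maximum in alphabet / canonical-pair order) is used.
    """
    B = np.asarray(B, dtype=np.float64)
    L = B.shape[0]
    if not (1 <= r.i <= L and 1 <= r.j <= L):
        raise IndexError(f"rule indices ({r.i},{r.j}) outside 1..{L}")
    i, j = r.i - 1, r.j - 1
    if r.rule_type == SS:
        ch = B[i, CHAR_COLUMN[r.left_char] - 1] if r.left_char else B[i, :6].max()
        return float(B[i, 6] * B[j, 7] * ch)
    if r.rule_type == ST:
        return float(B[i, 8] * B[j, 9])
    if r.rule_type == TT:
        ch = B[j, CHAR_COLUMN[r.right_char] - 1] if r.right_char else B[j, :6].max()
        return float(B[i, 10] * B[j, 11] * ch)
    if r.rule_type == TU:
        return float(B[i, 12] * B[j, 13])
    if r.rule_type == TB:
        return float(B[i, 14] * B[j, 15] * B[r.k - 1, 16])
    if r.rule_type == US:
        if r.left_char and r.right_char:
            return float(
                B[i, CHAR_COLUMN[r.left_char] - 1] * B[j, CHAR_COLUMN[r.right_char] - 1]
            )
        return max(float(B[i, a] * B[j, b]) for a, b in _PAIR_COLS)
    raise ValueError(f"unknown rule type {r.rule_type}")


def score_tree(B: np.ndarray, t: ParseTree) -> float:
    """Product of :func:`rule_score` over the tree's rules."""
    score = 1.0
    for r in t.rules:
        score *= rule_score(B, r)
    return score


# ---------------------------------------------------------------------------
# Dynamic program
# ---------------------------------------------------------------------------

class _Scores:
    """Precomputed vectorized rule-score factors for one matrix."""

    def __init__(self, B: np.ndarray):
        self.B = B
        L = B.shape[0]
        self.L = L
        # Best emission character per row (first max = alphabet order).
        self.bn_best = B[:, :6].max(axis=1)
        self.bn_arg = B[:, :6].argmax(axis=1)
        # Best pair characters per (i, j): max over the six canonical pairs.
        us = np.empty((6, L, L))
        for p, (a, b) in enumerate(_PAIR_COLS):
            us[p] = np.outer(B[:, a], B[:, b])
        self.us_best = us.max(axis=0)
        self.us_arg = us.argmax(axis=0)
        # Two-factor span scores as outer products.
        self.ss = np.outer(B[:, 6] * self.bn_best, B[:, 7])
        self.st = np.outer(B[:, 8], B[:, 9])
        self.tt = np.outer(B[:, 10], B[:, 11] * self.bn_best)
        self.tu = np.outer(B[:, 12], B[:, 13])
        # tb factors: row i of col 15, row j of col 16, row k of col 17.
        self.tb_i = B[:, 14]
        self.tb_j = B[:, 15]
        self.tb_k = B[:, 16]


def _fill_tables(sc: _Scores) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    L = sc.L
    M_S = np.full((L, L), IMPOSSIBLE)
    M_T = np.full((L, L), IMPOSSIBLE)
    M_U = np.full((L, L), IMPOSSIBLE)
    for i in range(L):
        M_S[i, i] = sc.ss[i, i]
    for span in range(1, L):  # span = j - i (0-based)
        for i in range(L - span):
            j = i + span
            if span >= 2:
                # U[i,j] = S[i+1,j-1] * best pair score.
                M_U[i, j] = M_S[i + 1, j - 1] * sc.us_best[i, j]
                # T[i,j]: tt, then tu, then tb splits in increasing k.
                best = IMPOSSIBLE
                if span >= 3 and M_T[i, j - 1] != IMPOSSIBLE:
                    best = M_T[i, j - 1] * sc.tt[i, j]
                cand = M_U[i, j] * sc.tu[i, j]
                if cand > best:
                    best = cand
                if span >= 5:
                    ks = np.arange(i + 2, j - 2)  # i+2 <= k <= j-3
                    # association must match the traceback's recomputation
                    cands = (
                        M_T[i, ks] * M_U[ks + 1, j] * sc.tb_i[i] * sc.tb_j[j]
                        * sc.tb_k[ks]
                    )
                    kmax = cands.max()
                    if kmax > best:
                        best = kmax
                M_T[i, j] = best
            # S[i,j]: ss first, st replaces only if strictly greater.
            best = M_S[i + 1, j] * sc.ss[i, j]
            if span >= 2:
                cand = M_T[i, j] * sc.st[i, j]
                if cand > best:
                    best = cand
            M_S[i, j] = best
    return M_S, M_T, M_U


def decode_max(B: np.ndarray) -> DecodedResult:
    """Recover the maximum-score parse tree of ``B`` by dynamic
    programming with traceback.

    A complete parse always exists (the all-``ss`` chain), possibly with
    score 0.  The returned rule list is in pre-order, matching
    :func:`rnagvae.grammar.parse`.
    """
    B = _check_matrix(B)
    sc = _Scores(B)
    L = sc.L
    M_S, M_T, M_U = _fill_tables(sc)

    rules: list[ProductionRule] = []

    def char_at(row: int) -> str:
        return ALPHABET[sc.bn_arg[row]]

    def trace_S(i: int, j: int) -> None:
        if i == j:
            rules.append(ProductionRule(SS, i + 1, j + 1, left_char=char_at(i)))
            return
        target = M_S[i, j]
        if M_S[i + 1, j] * sc.ss[i, j] == target:
            rules.append(ProductionRule(SS, i + 1, j + 1, left_char=char_at(i)))
            trace_S(i + 1, j)
        else:
            rules.append(ProductionRule(ST, i + 1, j + 1))
            trace_T(i, j)

    def trace_T(i: int, j: int) -> None:
        target = M_T[i, j]
        span = j - i
        if span >= 3 and M_T[i, j - 1] != IMPOSSIBLE:
            if M_T[i, j - 1] * sc.tt[i, j] == target:
                rules.append(ProductionRule(TT, i + 1, j + 1, right_char=char_at(j)))
                trace_T(i, j - 1)
                return
        if M_U[i, j] * sc.tu[i, j] == target:
            rules.append(ProductionRule(TU, i + 1, j + 1))
            trace_U(i, j)
            return
        for k in range(i + 2, j - 2):
            cand = M_T[i, k] * M_U[k + 1, j] * sc.tb_i[i] * sc.tb_j[j] * sc.tb_k[k]
            if cand == target:
                rules.append(ProductionRule(TB, i + 1, j + 1, k=k + 1))
                trace_T(i, k)
                trace_U(k + 1, j)
                return
        raise RuntimeError(f"traceback failed at T[{i + 1},{j + 1}]")

    def trace_U(i: int, j: int) -> None:
        pair = CANONICAL_PAIRS[sc.us_arg[i, j]]
        rules.append(
            ProductionRule(US, i + 1, j + 1, left_char=pair[0], right_char=pair[1])
        )
        trace_S(i + 1, j - 1)

    trace_S(0, L - 1)
    tree = ParseTree(rules, L)
    return DecodedResult(tree=tree, rna=realize(tree), score=float(M_S[0, L - 1]))


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_max(B: np.ndarray) -> DecodedResult:
    """Exhaustive maximum over all derivation skeletons (guarded L <= 8).

    Characters are maximized per rule, which is exact because each rule's
    character factors are private to that rule.  Skeletons are enumerated
    in the decoder's tie-break order, so the first maximum matches
    :func:`decode_max` on ties.
    """
    B = _check_matrix(B)
    L = B.shape[0]
    best_score = -np.inf
    best_rules: list[ProductionRule] | None = None
    for skeleton in enumerate_tree_shapes(L):
        score = 1.0
        for r in skeleton:
            score *= rule_score(B, r)
        if score > best_score:
            best_score = score
            best_rules = skeleton
    assert best_rules is not None
    filled = [_fill_chars(B, r) for r in best_rules]
    tree = ParseTree(filled, L)
    return DecodedResult(tree=tree, rna=realize(tree), score=float(best_score))


def _fill_chars(B: np.ndarray, r: ProductionRule) -> ProductionRule:
    i, j = r.i - 1, r.j - 1
    if r.rule_type == SS:
        return ProductionRule(SS, r.i, r.j, left_char=ALPHABET[B[i, :6].argmax()])
    if r.rule_type == TT:
        return ProductionRule(TT, r.i, r.j, right_char=ALPHABET[B[j, :6].argmax()])
    if r.rule_type == US:
        scores = [B[i, a] * B[j, b] for a, b in _PAIR_COLS]
        pair = CANONICAL_PAIRS[int(np.argmax(scores))]
        return ProductionRule(US, r.i, r.j, left_char=pair[0], right_char=pair[1])
    return r
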