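"""Unambiguous context-free grammar for nested RNA secondary structure.

The grammar is a position-indexed variant of the classic unambiguous G4
grammar.  Three non-terminals are used: ``S`` (may emit unpaired bases on
its left edge), ``T`` (ends in a pair or bifurcation) and ``U`` (a base
pair).  With 1-based inclusive spans ``[i, j]`` the productions are::

    ss: S[i,j] -> n S[i+1,j]          (terminal form S[i,i] -> n)
    st: S[i,j] -> T[i,j]
    tt: T[i,j] -> T[i,j-1] n
    tu: T[i,j] -> U[i,j]
    tb: T[i,j] -> T[i,k] U[k+1,j]
    us: U[i,j] -> n S[i+1,j-1] n'

where ``n`` ranges over the six-letter alphabet ``a c g u - x`` ('-' is an
alignment gap, 'x' a 3'-padding letter) and ``n n'`` over the canonical
pairs (Watson-Crick plus GU wobble).  Because the grammar is unambiguous,
every (sequence, structure) pair has exactly one derivation, which this
module computes (`parse`) and inverts (`realize`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

logger = logging.getLogger(__name__)

#: Terminal alphabet in column order: nucleotides, alignment gap, padding.
ALPHABET = "acgu-x"

#: 1-based matrix column of each terminal character.
CHAR_COLUMN = {ch: idx + 1 for idx, ch in enumerate(ALPHABET)}

#: Canonical base pairs (Watson-Crick plus GU wobble), in deterministic
#: tie-break order.
CANONICAL_PAIRS = ("au", "ua", "cg", "gc", "gu", "ug")

_PAIR_SET = frozenset(CANONICAL_PAIRS)

#: Rule-type names.
SS, ST, TT, TU, TB, US = "SS", "ST", "TT", "TU", "TB", "US"


@dataclass(frozen=True)
class RnaInput:
    """A sequence over ``{a,c,g,u,-,x}`` with a same-length dot-bracket
    structure.  Positions are 1-based throughout the public API."""

    sequence: str
    structure: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.structure):
            raise ValueError(
                f"sequence length {len(self.sequence)} != "
                f"structure length {len(self.structure)}"
            )
        if len(self.sequence) == 0:
            raise ValueError("empty input")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ProductionRule:
    """One grammar production with its 1-based span and emitted characters.

    ``SS`` emits ``left_char`` at ``i`` (the terminal form has ``i == j``);
    ``TT`` emits ``right_char`` at ``j``; ``US`` emits both pair partners;
    ``ST``/``TU``/``TB`` emit nothing.  ``k`` is the bifurcation split of
    ``TB`` (last position of the left ``T`` child).
    """

    rule_type: str
    i: int
    j: int
    k: Optional[int] = None
    left_char: Optional[str] = None
    right_char: Optional[str] = None

    def skeleton(self) -> "ProductionRule":
        """The rule with emitted characters erased (indices kept)."""
        return ProductionRule(self.rule_type, self.i, self.j, self.k)


@dataclass
class ParseTree:
    """The unique derivation of an :class:`RnaInput`, as a pre-order rule
    list rooted at ``S[1,L]``."""

    rules: list[ProductionRule]
    length: int

    def emitted_positions(self) -> list[int]:
        """Multiset of positions emitted by the rules (valid trees cover
        ``1..L`` exactly once)."""
        out: list[int] = []
        for r in self.rules:
            if r.rule_type == SS:
                out.append(r.i)
            elif r.rule_type == TT:
                out.append(r.j)
            elif r.rule_type == US:
                out.extend((r.i, r.j))
        return out

    def pair_count(self) -> int:
        return sum(1 for r in self.rules if r.rule_type == US)


# ---------------------------------------------------------------------------
# Structure utilities
# ---------------------------------------------------------------------------

_EXTRA_BRACKETS = {"[": "]", "{": "}", "<": ">"}


def normalize_brackets(structure: str) -> str:
    """Reduce a multi-layer bracket annotation to plain ``().`` notation.

    Any bracket layer beyond the first (``[]``, ``{}``, ``<>``, ``Aa`` ...)
    marks crossing (pseudoknotted) pairs that a context-free grammar cannot
    represent; those positions are converted to unpaired with a warning.
    """
    out = []
    dropped = 0
    for ch in structure:
        if ch in "().":
            out.append(ch)
        else:
            out.append(".")
            if ch not in ",_-:~":  # common unpaired glyphs are silent
                dropped += 1
    if dropped:
        logger.warning(
            "dropped %d pseudoknot/extra-layer bracket positions", dropped
        )
    return "".join(out)


def pair_table(structure: str) -> list[Optional[int]]:
    """Map each 0-based position to its 0-based partner (None if unpaired).

    Raises ``ValueError`` on unbalanced brackets.
    """
    partner: list[Optional[int]] = [None] * len(structure)
    stack: list[int] = []
    for pos, ch in enumerate(structure):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {pos + 1}")
            op = stack.pop()
            partner[op] = pos
            partner[pos] = op
        elif ch != ".":
            raise ValueError(f"illegal structure character {ch!r}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1] + 1}")
    return partner


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_input(x: RnaInput) -> list[str]:
    """Check every grammar invariant; an empty report means parseable.

    Violations reported: illegal characters, unbalanced or non-nested
    brackets, pairs with an empty interior (``()``), gap/padding characters
    inside a pair, and non-canonical pairs.
    """
    report: list[str] = []
    seq = x.sequence
    for pos, ch in enumerate(seq):
        if ch not in ALPHABET:
            report.append(f"illegal character {ch!r} at position {pos + 1}")
    try:
        partner = pair_table(x.structure)
    except ValueError as exc:
        report.append(str(exc))
        return report
    for pos, q in enumerate(partner):
        if q is None or q < pos:
            continue
        i, j = pos + 1, q + 1
        if q == pos + 1:
            report.append(f"pair ({i},{j}) has an empty interior")
        a, b = seq[pos], seq[q]
        if a in "-x" or b in "-x":
            report.append(f"pair ({i},{j}) involves gap/padding {a}{b}")
        elif a + b not in _PAIR_SET:
            report.append(f"non-canonical pair {a}{b} at ({i},{j})")
    return report


# ---------------------------------------------------------------------------
# Parsing (the unique derivation)
# ---------------------------------------------------------------------------

def parse(x: RnaInput) -> ParseTree:
    """Return THE derivation of ``x`` under the grammar.

    The grammar is unambiguous, so the derivation is forced: an unpaired
    left edge uses ``ss``; a ``T`` span trims unpaired right bases with
    ``tt``, closes an outermost pair spanning the whole span with
    ``tu``/``us``, and otherwise bifurcates with ``tb`` just before the
    opening bracket of the rightmost outermost pair.
    """
    problems = validate_input(x)
    if problems:
        raise ValueError("invalid input: " + "; ".join(problems))
    seq = x.sequence
    partner = pair_table(x.structure)
    L = len(seq)
    rules: list[ProductionRule] = []

    def derive_S(i: int, j: int) -> None:
        # 1-based inclusive span; i <= j guaranteed for valid inputs.
        if i == j:
            rules.append(ProductionRule(SS, i, i, left_char=seq[i - 1]))
            return
        if partner[i - 1] is None:
            rules.append(ProductionRule(SS, i, j, left_char=seq[i - 1]))
            derive_S(i + 1, j)
        else:
            rules.append(ProductionRule(ST, i, j))
            derive_T(i, j)

    def derive_T(i: int, j: int) -> None:
        if partner[j - 1] is None:
            rules.append(ProductionRule(TT, i, j, right_char=seq[j - 1]))
            derive_T(i, j - 1)
            return
        q = partner[j - 1] + 1  # 1-based opening partner of j
        if q == i:
            rules.append(ProductionRule(TU, i, j))
            derive_U(i, j)
        elif q < i:
            raise ValueError(f"crossing pair at span ({i},{j})")
        else:
            k = q - 1
            rules.append(ProductionRule(TB, i, j, k=k))
            derive_T(i, k)
            derive_U(k + 1, j)

    def derive_U(i: int, j: int) -> None:
        rules.append(
            ProductionRule(US, i, j, left_char=seq[i - 1], right_char=seq[j - 1])
        )
        derive_S(i + 1, j - 1)

    derive_S(1, L)
    return ParseTree(rules, L)


# ---------------------------------------------------------------------------
# Realization (inverse of parse)
# ---------------------------------------------------------------------------

def realize(t: ParseTree) -> RnaInput:
    """Rebuild the (sequence, structure) pair a tree derives.

    Every position must be emitted exactly once; ``US`` positions become
    ``(`` / ``)``, all others ``.``.
    """
    L = t.length
    seq: list[Optional[str]] = [None] * L
    struct = ["."] * L

    def emit(pos: int, ch: str, bracket: Optional[str] = None) -> None:
        if not 1 <= pos <= L:
            raise ValueError(f"emitted position {pos} outside 1..{L}")
        if seq[pos - 1] is not None:
            raise ValueError(f"position {pos} emitted twice")
        seq[pos - 1] = ch
        if bracket:
            struct[pos - 1] = bracket

    for r in t.rules:
        if r.rule_type == SS:
            emit(r.i, r.left_char)
        elif r.rule_type == TT:
            emit(r.j, r.right_char)
        elif r.rule_type == US:
            emit(r.i, r.left_char, "(")
            emit(r.j, r.right_char, ")")
    missing = [p + 1 for p, ch in enumerate(seq) if ch is None]
    if missing:
        raise ValueError(f"positions never emitted: {missing}")
    return RnaInput("".join(seq), "".join(struct))


# ---------------------------------------------------------------------------
# Skeleton enumeration (brute-force oracle support)
# ---------------------------------------------------------------------------

_ENUM_GUARD = 8


def enumerate_tree_shapes(L: int) -> list[list[ProductionRule]]:
    """All derivation skeletons (rules with indices, characters erased)
    the grammar admits for length ``L``.

    Exponential in ``L``; guarded at ``L <= 8``.  Enumeration follows the
    same deterministic preference order as the DP decoder (``ss`` before
    ``st``; ``tt`` before ``tu`` before ``tb``; ``tb`` splits in
    increasing ``k``) so that the first maximum found by the brute-force
    oracle matches the decoder's tie-break.
    """
    if L > _ENUM_GUARD:
        raise ValueError(f"L={L} exceeds enumeration guard {_ENUM_GUARD}")
    if L < 1:
        raise ValueError("L must be >= 1")

    s_memo: dict[tuple[int, int], list[list[ProductionRule]]] = {}
    t_memo: dict[tuple[int, int], list[list[ProductionRule]]] = {}

    def enum_S(i: int, j: int) -> list[list[ProductionRule]]:
        key = (i, j)
        if key in s_memo:
            return s_memo[key]
        out: list[list[ProductionRule]] = []
        if i == j:
            out.append([ProductionRule(SS, i, i)])
        else:
            head = ProductionRule(SS, i, j)
            for tail in enum_S(i + 1, j):
                out.append([head] + tail)
            if j - i >= 2:
                head = ProductionRule(ST, i, j)
                for tail in enum_T(i, j):
                    out.append([head] + tail)
        s_memo[key] = out
        return out

    def enum_T(i: int, j: int) -> list[list[ProductionRule]]:
        key = (i, j)
        if key in t_memo:
            return t_memo[key]
        out: list[list[ProductionRule]] = []
        if j - i >= 3:
            head = ProductionRule(TT, i, j)
            for tail in enum_T(i, j - 1):
                out.append([head] + tail)
        if j - i >= 2:
            head = ProductionRule(TU, i, j)
            us = ProductionRule(US, i, j)
            for tail in enum_S(i + 1, j - 1):
                out.append([head, us] + tail)
        for k in range(i + 2, j - 2):  # i+2 <= k <= j-3
            head = ProductionRule(TB, i, j, k=k)
            us = ProductionRule(US, k + 1, j)
            for left in enum_T(i, k):
                for inner in enum_S(k + 2, j - 1):
                    out.append([head] + left + [us] + inner)
        t_memo[key] = out
        return out

    return enum_S(1, L)


def count_tree_shapes(L: int) -> int:
    """Number of skeletons of length ``L`` by a direct recursion (an
    independent check on :func:`enumerate_tree_shapes`)."""

    s_memo: dict[tuple[int, int], int] = {}
    t_memo: dict[tuple[int, int], int] = {}

    def cnt_S(i: int, j: int) -> int:
        if i == j:
            return 1
        key = (i, j)
        if key not in s_memo:
            total = cnt_S(i + 1, j)
            if j - i >= 2:
                total += cnt_T(i, j)
            s_memo[key] = total
        return s_memo[key]

    def cnt_T(i: int, j: int) -> int:
        key = (i, j)
        if key not in t_memo:
            total = 0
            if j - i >= 3:
                total += cnt_T(i, j - 1)
            if j - i >= 2:
                total += cnt_S(i + 1, j - 1)
            for k in range(i + 2, j - 2):
                total += cnt_T(i, k) * cnt_S(k + 2, j - 1)
            t_memo[key] = total
        return t_memo[key]

    return cnt_S(1, L)
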