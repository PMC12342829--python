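"""Reading, filtering and preparing training data.

Two preparation modes mirror the two ways a family can be modeled:

* ``unaligned`` — alignment gaps are removed from every sequence and the
  padding letter ``x`` is appended at the 3' end up to the family-wide
  maximum length ``L``;
* ``aligned`` — gaps are kept as the explicit ``-`` character and all
  records must already share one length.

Records are excluded (and counted per reason) when the sequence contains
letters other than a, c, g, u (e.g. ``n``), when the structure cannot be
derived by the grammar (e.g. an adjacent ``()`` pair), or when the exact
sequence was already seen (duplicates are kept once).  Base pairs whose
characters are not canonical, or that involve a gap, are opened to
unpaired during reading, so Stockholm consensus structures project
cleanly onto individual sequences.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import AlignIO

from . import codec
from .grammar import RnaInput, pair_table, parse, validate_input

logger = logging.getLogger(__name__)

_GAP_CHARS = "-._~"
#: WUSS bracket layers that mark nested consensus pairs.
_WUSS_OPEN = "<([{"
_WUSS_CLOSE = ">)]}"
_CANONICAL = {"au", "ua", "cg", "gc", "gu", "ug"}


@dataclass
class Record:
    """One input RNA: id, sequence, dot-bracket structure, optional
    activity."""

    id: str
    sequence: str
    structure: str
    activity: Optional[float] = None


@dataclass
class DatasetSpec:
    """A prepared, encodable dataset of common length ``L``."""

    mode: str
    records: list[Record]
    L: int
    filter_report: dict[str, int] = field(default_factory=dict)
    matrices: Optional[np.ndarray] = None  # (n, L, 17)

    @property
    def activities(self) -> Optional[np.ndarray]:
        vals = [r.activity for r in self.records]
        if any(v is None for v in vals):
            return None
        return np.array(vals, dtype=np.float64)


# ---------------------------------------------------------------------------
# Dot-bracket ("Vienna") records
# ---------------------------------------------------------------------------

def read_vienna(source: Union[str, Path, io.TextIOBase]) -> list[Record]:
    """Read id / sequence / structure triplets (``>id`` header lines)."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    records: list[Record] = []
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    pos = 0
    while pos < len(lines):
        if not lines[pos].startswith(">"):
            raise ValueError(f"expected '>' header, got {lines[pos]!r}")
        if pos + 2 >= len(lines):
            raise ValueError(f"truncated record {lines[pos]!r}")
        records.append(
            Record(id=lines[pos][1:].split()[0], sequence=lines[pos + 1],
                   structure=lines[pos + 2])
        )
        pos += 3
    return records


def write_vienna(records: Iterable[Record], dest: Union[str, Path, io.TextIOBase]) -> None:
    text = "".join(f">{r.id}\n{r.sequence}\n{r.structure}\n" for r in records)
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)


# ---------------------------------------------------------------------------
# Stockholm alignments
# ---------------------------------------------------------------------------

def consensus_to_dotbracket(ss_cons: str) -> str:
    """Convert a WUSS consensus line to plain dot-bracket.

    All nested bracket layers (``<>``, ``()``, ``[]``, ``{}``) become
    ``()``; letters mark pseudoknots, which a context-free grammar cannot
    represent, and are dropped to unpaired with a warning.
    """
    out = []
    knots = 0
    for ch in ss_cons:
        if ch in _WUSS_OPEN:
            out.append("(")
        elif ch in _WUSS_CLOSE:
            out.append(")")
        elif ch.isalpha():
            knots += 1
            out.append(".")
        else:
            out.append(".")
    if knots:
        logger.warning("dropped %d pseudoknot positions from consensus", knots)
    return "".join(out)


def project_structure(sequence: str, consensus: str) -> str:
    """Per-sequence structure from a consensus dot-bracket.

    A consensus pair is kept only when the sequence's two characters form
    a canonical pair; pairs involving a gap or a non-canonical combination
    are opened to unpaired for that sequence.
    """
    partner = pair_table(consensus)
    struct = ["."] * len(sequence)
    for i, q in enumerate(partner):
        if q is None or q < i:
            continue
        a, b = sequence[i], sequence[q]
        if a + b in _CANONICAL:
            struct[i], struct[q] = "(", ")"
    return "".join(struct)


def read_stockholm(source: Union[str, Path, io.TextIOBase]) -> list[Record]:
    """Read a Stockholm alignment, projecting the ``SS_cons`` consensus
    structure onto each aligned sequence.

    Sequences are lowercased with ``t`` mapped to ``u`` and all gap
    dialect characters normalized to ``-``.
    """
    handle = open(source) if isinstance(source, (str, Path)) else source
    try:
        aln = AlignIO.read(handle, "stockholm")
    finally:
        if isinstance(source, (str, Path)):
            handle.close()
    ss = aln.column_annotations.get("secondary_structure")
    if ss is None:
        raise ValueError("alignment has no SS_cons consensus-structure line")
    consensus = consensus_to_dotbracket(ss)
    pair_table(consensus)  # raises on an unbalanced consensus
    records = []
    for row in aln:
        seq = normalize_sequence(str(row.seq))
        records.append(
            Record(id=row.id, sequence=seq, structure=project_structure(seq, consensus))
        )
    return records


# ---------------------------------------------------------------------------
# Preparation
# ---------------------------------------------------------------------------

def normalize_sequence(seq: str) -> str:
    """Lowercase, map t->u (DNA-style input) and normalize gap glyphs."""
    out = []
    for ch in seq.lower():
        if ch == "t":
            ch = "u"
        elif ch in _GAP_CHARS:
            ch = "-"
        out.append(ch)
    return "".join(out)


def strip_gaps(sequence: str, structure: str) -> tuple[str, str]:
    """Drop gap columns (their structure entries, always unpaired, drop
    with them)."""
    keep = [p for p, ch in enumerate(sequence) if ch != "-"]
    return (
        "".join(sequence[p] for p in keep),
        "".join(structure[p] for p in keep),
    )


def prepare(
    records: Sequence[Record],
    mode: str = "unaligned",
    encode: bool = True,
) -> DatasetSpec:
    """Filter and length-standardize records, optionally encoding them.

    Exclusion reasons counted in ``filter_report``: ``non_acgu`` (letters
    other than a/c/g/u beyond gaps), ``unparseable`` (structure the
    grammar cannot derive), ``duplicate`` (same final sequence seen
    before).  The report always satisfies
    ``input == kept + sum(exclusions)``.
    """
    if mode not in ("aligned", "unaligned"):
        raise ValueError(f"unknown mode {mode!r}")
    report = {"non_acgu": 0, "unparseable": 0, "duplicate": 0}
    staged: list[Record] = []
    for rec in records:
        seq = normalize_sequence(rec.sequence)
        struct = rec.structure
        if len(seq) != len(struct):
            report["unparseable"] += 1
            continue
        bases = set(seq) - set("-x")
        if not bases <= set("acgu"):
            report["non_acgu"] += 1
            continue
        if mode == "unaligned":
            seq, struct = strip_gaps(seq, struct)
            if not seq:
                report["unparseable"] += 1
                continue
        staged.append(Record(rec.id, seq, struct, rec.activity))

    if mode == "aligned":
        lengths = {len(r.sequence) for r in staged}
        if len(lengths) > 1:
            raise ValueError(f"aligned mode requires equal lengths, got {sorted(lengths)}")
    L = max((len(r.sequence) for r in staged), default=0)

    kept: list[Record] = []
    seen: set[str] = set()
    for rec in staged:
        seq, struct = rec.sequence, rec.structure
        pad = L - len(seq)
        if pad:
            seq += "x" * pad
            struct += "." * pad
        if seq in seen:
            report["duplicate"] += 1
            continue
        x = RnaInput(seq, struct)
        if validate_input(x):
            report["unparseable"] += 1
            continue
        seen.add(seq)
        kept.append(Record(rec.id, seq, struct, rec.activity))

    spec = DatasetSpec(mode=mode, records=kept, L=L, filter_report=report)
    if encode and kept:
        spec.matrices = np.stack(
            [codec.encode(parse(RnaInput(r.sequence, r.structure)), L) for r in kept]
        ).astype(np.float64)
    return spec


# ---------------------------------------------------------------------------
# Activity tables
# ---------------------------------------------------------------------------

def read_activity(
    source: Union[str, Path, io.TextIOBase], normalize: bool = True
) -> dict[str, float]:
    """Two-column (id, activity) TSV, min-max normalized to [0, 1].

    Normalization is (x - min) / (max - min) per dataset; pass
    ``normalize=False`` for pre-normalized input.  A constant column (or
    a single record) has no defined normalization and raises.
    """
    df = pd.read_csv(source, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError("activity table needs two columns: id, value")
    ids = df.iloc[:, 0].astype(str)
    try:
        vals = df.iloc[:, 1].astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric activity value: {exc}") from exc
    if normalize:
        lo, hi = vals.min(), vals.max()
        if hi == lo:
            raise ValueError("constant activities: normalization undefined")
        vals = (vals - lo) / (hi - lo)
    elif vals.min() < 0 or vals.max() > 1:
        raise ValueError("pre-normalized activities must lie in [0, 1]")
    return dict(zip(ids, vals))


def attach_activities(records: Sequence[Record], table: dict[str, float]) -> None:
    """Set ``record.activity`` from an id-keyed table (missing id raises)."""
    for rec in records:
        if rec.id not in table:
            raise KeyError(f"no activity for record {rec.id!r}")
        rec.activity = float(table[rec.id])


def write_filter_report(report: dict[str, int], dest: Union[str, Path, io.TextIOBase]) -> None:
    text = "reason\tcount\n" + "".join(f"{k}\t{v}\n" for k, v in report.items())
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)
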