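"""Synthetic RNA families with structure-dependent activities.

The generator emulates the kind of data the model is built for: a family
of related sequences of bounded length whose individual nested secondary
structures vary (as in a mutant library where local mutations rearrange
whole stems), plus an activity that is a noisy deterministic function of
a structural feature — here, the fraction of a designated target stem's
base pairs present in a sequence's structure.

Structures are built by a seeded stochastic grammar walk and are valid
by construction (hairpin loops of at least ``min_loop`` bases, never an
adjacent ``()`` pair), so every fixture parses, encodes and survives
:func:`rnagvae.pipeline.prepare` with zero exclusions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .grammar import CANONICAL_PAIRS, RnaInput, pair_table, validate_input
from .pipeline import Record

_BASES = "acgu"


@dataclass
class FamilySpec:
    """Parameters of a synthetic family.

    ``mutation_rate`` substitutes unpaired positions only (validity is
    preserved); ``structure_perturb_prob`` is the per-sequence chance of
    opening one whole stem of the consensus, so structural variation is
    stem-scale, not single-pair.
    """

    n: int = 50
    consensus_structure: str = ""
    mutation_rate: float = 0.1
    structure_perturb_prob: float = 0.3
    seed: int = 0


@dataclass
class ActivityModel:
    """Activity = fraction of ``target_stem`` pairs present, plus
    Gaussian noise of sd ``noise_sd``, clipped to [0, 1].  Pairs are
    0-based (i, j) tuples."""

    target_stem: tuple[tuple[int, int], ...]
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# Random structures
# ---------------------------------------------------------------------------

def random_structure(L: int, seed: int, min_loop: int = 3) -> str:
    """A seeded random nested structure of length ``L``, always
    grammar-parseable (loops of at least ``max(min_loop, 1)``)."""
    if L < 1:
        raise ValueError("L must be >= 1")
    min_loop = max(min_loop, 1)
    rng = np.random.default_rng(seed)

    def walk(length: int) -> str:
        if length == 0:
            return ""
        if length >= min_loop + 2 and rng.random() < 0.6:
            span = int(rng.integers(min_loop + 2, length + 1))
            return "(" + walk(span - 2) + ")" + walk(length - span)
        return "." + walk(length - 1)

    return walk(L)


def stems(structure: str) -> list[list[tuple[int, int]]]:
    """Maximal stacks of directly nested adjacent pairs, as 0-based
    (i, j) lists ordered by opening position."""
    pt = pair_table(structure)
    pairs = sorted((i, q) for i, q in enumerate(pt) if q is not None and q > i)
    out: list[list[tuple[int, int]]] = []
    for p in pairs:
        if out and out[-1][-1] == (p[0] - 1, p[1] + 1):
            out[-1].append(p)
        else:
            out.append([p])
    return out


def _open_stem(structure: str, stem: list[tuple[int, int]]) -> str:
    s = list(structure)
    for i, j in stem:
        s[i] = s[j] = "."
    return "".join(s)


# ---------------------------------------------------------------------------
# Families
# ---------------------------------------------------------------------------

def make_family(spec: FamilySpec, unique: bool = True) -> list[Record]:
    """Generate ``n`` related sequences around a consensus.

    One consensus sequence is drawn for the family (random canonical
    pairs at paired positions, random bases elsewhere), so members share
    high nucleotide identity like a natural family or a mutant library.
    Per sequence the consensus structure is optionally perturbed by
    opening one random whole stem, then substitutions at
    ``mutation_rate`` hit currently unpaired positions only (validity is
    preserved).  With ``unique`` (default) duplicate sequences are
    retried a bounded number of times and exhaustion raises; pass
    ``unique=False`` for degenerate zero-rate families of clones.
    """
    consensus = spec.consensus_structure
    if not consensus:
        raise ValueError("consensus_structure is required")
    rng = np.random.default_rng(spec.seed)
    consensus_seq = _fill_sequence(consensus, rng)
    problems = validate_input(RnaInput(consensus_seq, consensus))
    if problems:
        raise ValueError("consensus not derivable by the grammar: "
                         + "; ".join(problems))
    consensus_stems = stems(consensus)
    records: list[Record] = []
    seen: set[str] = set()
    for idx in range(spec.n):
        for _attempt in range(200):
            struct = consensus
            if consensus_stems and rng.random() < spec.structure_perturb_prob:
                which = int(rng.integers(len(consensus_stems)))
                struct = _open_stem(consensus, consensus_stems[which])
            seq = _mutate(consensus_seq, struct, rng, spec.mutation_rate)
            if not unique or seq not in seen:
                break
        else:
            raise RuntimeError("could not generate a unique sequence; "
                               "family too constrained")
        seen.add(seq)
        records.append(Record(id=f"syn{idx:04d}", sequence=seq, structure=struct))
    return records


def _fill_sequence(structure: str, rng: np.random.Generator) -> str:
    pt = pair_table(structure)
    seq = [""] * len(structure)
    for i, q in enumerate(pt):
        if q is None:
            seq[i] = _BASES[rng.integers(4)]
        elif q > i:
            pair = CANONICAL_PAIRS[rng.integers(len(CANONICAL_PAIRS))]
            seq[i], seq[q] = pair[0], pair[1]
    return "".join(seq)


def _mutate(seq: str, structure: str, rng: np.random.Generator,
            mutation_rate: float) -> str:
    pt = pair_table(structure)
    out = list(seq)
    for i, q in enumerate(pt):
        if q is None and rng.random() < mutation_rate:
            choices = _BASES.replace(out[i], "")
            out[i] = choices[rng.integers(3)]
    return "".join(out)


# ---------------------------------------------------------------------------
# Activities
# ---------------------------------------------------------------------------

def simulate_activity(record: Record, model: ActivityModel, seed: int) -> float:
    """Noisy structure-determined activity in [0, 1]."""
    pt = pair_table(record.structure)
    present = {(i, q) for i, q in enumerate(pt) if q is not None and q > i}
    frac = sum(1 for p in model.target_stem if p in present) / len(model.target_stem)
    noise = np.random.default_rng(seed).normal(0.0, model.noise_sd) if model.noise_sd else 0.0
    return float(np.clip(frac + noise, 0.0, 1.0))


def make_activity_family(
    spec: FamilySpec,
    activity_model: Optional[ActivityModel] = None,
) -> tuple[list[Record], ActivityModel]:
    """A family whose activity tracks how much of the consensus pairing
    each member retains (by default the target set is every consensus
    pair, so opening any stem lowers activity in proportion to its
    size).  Activities are stored on the records."""
    records = make_family(spec)
    if activity_model is None:
        pt = pair_table(spec.consensus_structure)
        target = tuple((i, q) for i, q in enumerate(pt) if q is not None and q > i)
        if not target:
            raise ValueError("consensus has no pairs to anchor activity on")
        activity_model = ActivityModel(target_stem=target)
    for idx, rec in enumerate(records):
        rec.activity = simulate_activity(rec, activity_model, seed=spec.seed * 100003 + idx)
    return records, activity_model


def write_activity_tsv(records: list[Record], dest) -> None:
    """Emit the (id, activity) table in the dialect the pipeline reads."""
    from pathlib import Path

    text = "".join(f"{r.id}\t{r.activity}\n" for r in records)
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)
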