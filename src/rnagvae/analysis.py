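"""Latent-space generation and analysis.

Generation samples latent points from the standard-normal prior, decodes
each through the VAE decoder into a reconstructed matrix, recovers the
maximum-score parse tree, strips padding/gap characters and filters out
duplicates and exact matches to the training sequences.  Analysis
utilities cover Moran's I spatial autocorrelation of activities in the
latent space, grammar-channel noise injection, nucleotide-identity
statistics and sampling from a localized latent region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import Align
from sklearn.neighbors import NearestNeighbors

from .codec import N_NUC
from .decoder import decode_max
from .grammar import pair_table
from .vae import GrammarVAE, decode_latent, sample_prior


@dataclass
class GeneratedItem:
    sequence: str
    structure: str
    z: np.ndarray
    score: float


@dataclass
class GenerationSet:
    """Generated records plus provenance counts."""

    items: list[GeneratedItem]
    provenance: dict = field(default_factory=dict)

    def sequences(self) -> list[str]:
        return [it.sequence for it in self.items]


@dataclass
class MoranResult:
    I: float
    k: int
    n: int


def strip_padding(sequence: str, structure: str) -> tuple[str, str]:
    """Remove gap '-' and padding 'x' positions (always unpaired) from a
    decoded record."""
    keep = [p for p, ch in enumerate(sequence) if ch not in "-x"]
    return (
        "".join(sequence[p] for p in keep),
        "".join(structure[p] for p in keep),
    )


def _decode_points(model: GrammarVAE, points: np.ndarray) -> list[GeneratedItem]:
    items = []
    for z in points:
        result = decode_max(decode_latent(model, z))
        seq, struct = strip_padding(result.rna.sequence, result.rna.structure)
        items.append(GeneratedItem(seq, struct, z, result.score))
    return items


def _filter(items: list[GeneratedItem], training: set[str]) -> list[GeneratedItem]:
    seen: set[str] = set()
    kept = []
    for it in items:
        if it.sequence in seen or it.sequence in training:
            continue
        seen.add(it.sequence)
        kept.append(it)
    return kept


def generate(
    model: GrammarVAE,
    n: int,
    seed: int,
    training_set: Optional[Iterable[str]] = None,
) -> GenerationSet:
    """Sample ``n`` prior points, decode them, and drop duplicates and
    training matches.

    ``training_set`` holds training sequences (compared after stripping
    their own gaps/padding).  The result may contain fewer than ``n``
    items; the provenance records both counts.
    """
    training = {strip_padding(s, "." * len(s))[0] for s in training_set or ()}
    points = sample_prior(n, seed, model.cfg.latent_dim)
    items = _filter(_decode_points(model, points), training)
    return GenerationSet(
        items=items,
        provenance={
            "model_id": id(model),
            "seed": seed,
            "n_sampled": n,
            "n_after_filters": len(items),
        },
    )


def region_sample(
    model: GrammarVAE,
    center: np.ndarray,
    radius: float,
    n: int,
    seed: int,
    dedup: bool = False,
) -> GenerationSet:
    """Decode ``n`` points sampled uniformly from a latent-space ball.

    Supports comparing sequences generated from different latent regions
    (e.g. around high- and low-activity clusters).  Duplicates are kept
    by default so that the sample reflects local decoder behavior.
    """
    center = np.asarray(center, dtype=np.float64)
    d = model.cfg.latent_dim
    if center.shape != (d,):
        raise ValueError(f"center must have {d} dims")
    rng = np.random.default_rng(seed)
    direc = rng.standard_normal((n, d))
    direc /= np.maximum(np.linalg.norm(direc, axis=1, keepdims=True), 1e-30)
    radii = radius * rng.random(n) ** (1.0 / d)
    points = center + direc * radii[:, None]
    items = _decode_points(model, points)
    if dedup:
        items = _filter(items, set())
    return GenerationSet(
        items=items,
        provenance={
            "model_id": id(model),
            "seed": seed,
            "n_sampled": n,
            "n_after_filters": len(items),
            "center": center.tolist(),
            "radius": radius,
        },
    )


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------

def morans_i(
    points: np.ndarray,
    values: Sequence[float],
    k: int,
    symmetrize: bool = False,
) -> MoranResult:
    """Spatial autocorrelation of ``values`` over a binary k-nearest-
    neighbor graph in the latent space (Euclidean).

    I = (n / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

    with ``w_ij = 1`` when j is among the k nearest neighbors of i
    (directed weights; ``symmetrize=True`` ORs the graph with its
    transpose).
    """
    P = np.asarray(points, dtype=np.float64)
    x = np.asarray(values, dtype=np.float64)
    n = P.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    if x.shape != (n,):
        raise ValueError("one value per point required")
    if k < 1 or k >= n:
        raise ValueError(f"k must satisfy 1 <= k < n, got k={k}, n={n}")
    if np.allclose(x, x[0]):
        raise ValueError("constant values: Moran's I undefined")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(P)
    _, idx = nn.kneighbors(P)
    W = np.zeros((n, n))
    for i in range(n):
        for j in idx[i]:
            if j != i:
                W[i, j] = 1.0
        # if the point itself appeared (duplicates), the row may hold k+1
        # hits minus self; trim to exactly k by keeping the nearest.
        extra = int(W[i].sum()) - k
        if extra > 0:
            on = [j for j in idx[i][::-1] if W[i, j]]
            for j in on[:extra]:
                W[i, j] = 0.0
    if symmetrize:
        W = np.maximum(W, W.T)
    d = x - x.mean()
    w_total = W.sum()
    I = (n / w_total) * (d @ W @ d) / (d @ d)
    return MoranResult(I=float(I), k=k, n=n)


# ---------------------------------------------------------------------------
# Noise injection
# ---------------------------------------------------------------------------

def inject_noise(B: np.ndarray, rate: float, seed: int) -> np.ndarray:
    """Flip each grammar-block (Bg) bit independently with probability
    ``rate``; the nucleotide one-hots (Bn) are untouched."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    B = np.array(B, copy=True)
    rng = np.random.default_rng(seed)
    flips = rng.random(B[:, N_NUC:].shape) < rate
    B[:, N_NUC:] = np.where(flips, 1 - B[:, N_NUC:], B[:, N_NUC:])
    return B


def structure_f1(true_structure: str, predicted_structure: str) -> float:
    """F1 of predicted base pairs against the true pair set (1.0 when
    both are identical, also when both are pair-free)."""
    def pairs(s: str) -> set[tuple[int, int]]:
        pt = pair_table(s)
        return {(i, q) for i, q in enumerate(pt) if q is not None and q > i}

    t, p = pairs(true_structure), pairs(predicted_structure)
    if not t and not p:
        return 1.0
    if not t or not p:
        return 0.0
    tp = len(t & p)
    precision = tp / len(p)
    recall = tp / len(t)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


# ---------------------------------------------------------------------------
# Identity statistics
# ---------------------------------------------------------------------------

def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1.0
    al.mismatch_score = 0.0
    al.open_gap_score = -1.0
    al.extend_gap_score = -1.0
    return al


def sequence_identity(a: str, b: str) -> float:
    """Nucleotide identity from a global alignment, not counting gap
    columns (neither gap-gap nor gap-base) in the denominator."""
    if not a or not b:
        raise ValueError("empty sequence")
    aln = _aligner().align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    cols = [(x, y) for x, y in zip(sa, sb) if x != "-" and y != "-"]
    if not cols:
        return 0.0
    return sum(x == y for x, y in cols) / len(cols)


def identity_stats(
    seqs: Sequence[str],
    reference_set: Optional[Sequence[str]] = None,
) -> dict:
    """Pairwise-identity distribution and, with a reference set, each
    sequence's maximum identity to the reference (Max-NI)."""
    if not seqs:
        raise ValueError("no sequences")
    out: dict = {}
    if len(seqs) >= 2:
        pairwise = [
            sequence_identity(seqs[i], seqs[j])
            for i in range(len(seqs))
            for j in range(i + 1, len(seqs))
        ]
        out["pairwise"] = np.array(pairwise)
        out["median_pairwise"] = float(np.median(pairwise))
    if reference_set:
        max_ni = [
            max(sequence_identity(s, r) for r in reference_set) for s in seqs
        ]
        out["max_identity"] = np.array(max_ni)
        out["median_max_identity"] = float(np.median(max_ni))
    return out
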