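import numpy as np
import pytest

from rnagvae.grammar import RnaInput
from rnagvae.synthetic import FamilySpec, make_activity_family, random_structure
from rnagvae.synthetic import _fill_sequence
from rnagvae.pipeline import prepare


def random_valid_input(seed: int, L_min: int = 1, L_max: int = 30,
                       pad_prob: float = 0.3) -> RnaInput:
    """A seeded random (sequence, structure) pair, optionally 3'-padded."""
    rng = np.random.default_rng(seed)
    L = int(rng.integers(L_min, L_max + 1))
    struct = random_structure(L, seed=int(rng.integers(2**31)))
    seq = _fill_sequence(struct, rng)
    if rng.random() < pad_prob:
        pad = int(rng.integers(1, 6))
        seq += "x" * pad
        struct += "." * pad
    return RnaInput(seq, struct)


@pytest.fixture(scope="session")
def small_family():
    """The reference synthetic family: 50 related sequences, L = 40,
    stem-scale structural variation, structure-determined activities."""
    consensus = random_structure(40, seed=11)
    spec = FamilySpec(n=50, consensus_structure=consensus, mutation_rate=0.1,
                      structure_perturb_prob=0.3, seed=5)
    records, activity_model = make_activity_family(spec)
    dataset = prepare(records, "unaligned")
    return dataset, activity_model
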