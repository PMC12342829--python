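"""Synthetic family generator and structure-determined activities."""

import numpy as np
import pytest

from rnagvae.grammar import RnaInput, pair_table, validate_input
from rnagvae.pipeline import prepare
from rnagvae.synthetic import (
    ActivityModel,
    FamilySpec,
    make_activity_family,
    make_family,
    random_structure,
    simulate_activity,
    stems,
)


class TestRandomStructure:
    def test_single_position(self):
        assert random_structure(1, seed=0) == "."

    def test_short_lengths_cannot_pair(self):
        # a pair needs a loop of >= 3, impossible below L = 5
        for L in (2, 3, 4):
            for s in range(20):
                assert random_structure(L, seed=s) == "." * L

    @pytest.mark.parametrize("s", range(50))
    def test_always_parseable(self, s):
        struct = random_structure(30, seed=s)
        seq = "a" * 30  # characters irrelevant for bracket validity
        pt = pair_table(struct)
        for i, q in enumerate(pt):
            if q is not None and q > i:
                assert q - i - 1 >= 3  # loop constraint, excludes "()"

    def test_seeded_determinism(self):
        assert random_structure(25, seed=4) == random_structure(25, seed=4)


class TestMakeFamily:
    CONSENSUS = "((((...))))..((((...))))"

    def test_zero_rates_give_consensus_clones(self):
        spec = FamilySpec(n=4, consensus_structure=self.CONSENSUS,
                          mutation_rate=0.0, structure_perturb_prob=0.0, seed=1)
        records = make_family(spec, unique=False)
        assert all(r.structure == self.CONSENSUS for r in records)
        assert len({r.sequence for r in records}) == 1

    def test_unique_clones_impossible(self):
        spec = FamilySpec(n=4, consensus_structure=self.CONSENSUS,
                          mutation_rate=0.0, structure_perturb_prob=0.0, seed=1)
        with pytest.raises(RuntimeError, match="unique"):
            make_family(spec)

    def test_full_perturbation_always_opens_a_stem(self):
        spec = FamilySpec(n=20, consensus_structure=self.CONSENSUS,
                          mutation_rate=0.0, structure_perturb_prob=1.0, seed=2)
        records = make_family(spec, unique=False)
        n_stems = len(stems(self.CONSENSUS))
        assert n_stems == 2
        for r in records:
            assert len(stems(r.structure)) == n_stems - 1

    def test_members_are_related(self):
        spec = FamilySpec(n=10, consensus_structure=self.CONSENSUS,
                          mutation_rate=0.1, structure_perturb_prob=0.0, seed=3)
        records = make_family(spec)
        ref = records[0].sequence
        for r in records[1:]:
            same = sum(a == b for a, b in zip(ref, r.sequence))
            assert same / len(ref) > 0.5

    def test_every_member_valid_and_preparable(self, small_family):
        dataset, _ = small_family
        assert len(dataset.records) == 50
        assert sum(dataset.filter_report.values()) == 0
        for r in dataset.records:
            assert validate_input(RnaInput(r.sequence, r.structure)) == []

    def test_invalid_consensus_rejected(self):
        with pytest.raises(ValueError):
            make_family(FamilySpec(n=2, consensus_structure="(.)(", seed=0))


class TestActivity:
    def test_fraction_of_target_stem(self):
        model = ActivityModel(target_stem=((0, 10), (1, 9)), noise_sd=0.0)
        full = simulate_activity(
            _rec("((.......))"), model, seed=0)
        none = simulate_activity(_rec("..........."), model, seed=0)
        half = simulate_activity(_rec("(.........)"), model, seed=0)
        assert (full, none, half) == (1.0, 0.0, 0.5)

    def test_noise_is_clipped(self):
        model = ActivityModel(target_stem=((0, 10),), noise_sd=5.0)
        for s in range(10):
            val = simulate_activity(_rec("(.........)"), model, seed=s)
            assert 0.0 <= val <= 1.0

    def test_family_activities_track_structure(self, small_family):
        dataset, activity_model = small_family
        acts = dataset.activities
        assert acts is not None and acts.min() >= 0 and acts.max() <= 1
        assert acts.std() > 0

    def test_negative_noise_sd_rejected(self):
        with pytest.raises(ValueError):
            ActivityModel(target_stem=((0, 5),), noise_sd=-1.0)


def _rec(structure):
    from rnagvae.pipeline import Record
    from rnagvae.synthetic import _fill_sequence

    seq = _fill_sequence(structure, np.random.default_rng(0))
    return Record("t", seq, structure)
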