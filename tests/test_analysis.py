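"""Generation, Moran's I, noise injection and identity statistics."""

import numpy as np
import pytest

from rnagvae.analysis import (
    generate,
    identity_stats,
    inject_noise,
    morans_i,
    region_sample,
    sequence_identity,
    strip_padding,
    structure_f1,
)
from rnagvae.codec import encode
from rnagvae.grammar import RnaInput, pair_table, parse
from rnagvae.vae import ModelConfig, build_model


@pytest.fixture(scope="module")
def untrained_model():
    return build_model(ModelConfig(encoder_widths=(16, 12, 8), latent_dim=4, seed=2), L=12)


class TestGenerate:
    def test_pipeline_integrity_on_untrained_model(self, untrained_model):
        gen = generate(untrained_model, 5, seed=1)
        assert gen.provenance["n_sampled"] == 5
        for item in gen.items:
            pair_table(item.structure)  # balanced
            assert set(item.sequence) <= set("acgu")  # padding/gaps stripped
            assert len(item.sequence) == len(item.structure)

    def test_seed_reproducibility(self, untrained_model):
        a = generate(untrained_model, 6, seed=3)
        b = generate(untrained_model, 6, seed=3)
        assert a.sequences() == b.sequences()

    def test_no_duplicates_or_training_matches(self, untrained_model):
        raw = generate(untrained_model, 8, seed=4)
        seqs = raw.sequences()
        assert len(seqs) == len(set(seqs))
        if seqs:
            filtered = generate(untrained_model, 8, seed=4, training_set=[seqs[0]])
            assert seqs[0] not in filtered.sequences()
            assert filtered.provenance["n_after_filters"] <= len(seqs)

    def test_region_radius_zero_decodes_identically(self, untrained_model):
        center = np.zeros(4)
        gen = region_sample(untrained_model, center, radius=0.0, n=4, seed=5)
        assert len(set(gen.sequences())) == 1


class TestMoransI:
    def test_two_cluster_example_is_one(self):
        points = np.array([[0, 0], [0, 0.1], [9, 9], [9, 9.1]])
        res = morans_i(points, [0, 0, 1, 1], k=1)
        assert res.I == pytest.approx(1.0)
        assert (res.k, res.n) == (1, 4)

    def test_permutation_null_mean(self):
        rng = np.random.default_rng(0)
        points = rng.standard_normal((30, 8))
        values = rng.random(30)
        draws = [
            morans_i(points, values[np.random.default_rng(s).permutation(30)], k=5).I
            for s in range(200)
        ]
        assert abs(np.mean(draws) - (-1 / 29)) < 0.05

    def test_constant_values_rejected(self):
        points = np.random.default_rng(1).standard_normal((5, 2))
        with pytest.raises(ValueError, match="constant"):
            morans_i(points, [1.0] * 5, k=2)

    def test_k_bounds(self):
        points = np.random.default_rng(1).standard_normal((5, 2))
        with pytest.raises(ValueError):
            morans_i(points, [0, 1, 0, 1, 0], k=5)


class TestNoise:
    @pytest.fixture()
    def encoding(self):
        x = RnaInput("gaaucaaagaaucaaagaaucaaagaauca",
                     "(...)...(...)...(...)...(...).")
        return encode(parse(x))

    def test_rate_zero_is_identity(self, encoding):
        assert np.array_equal(inject_noise(encoding, 0.0, seed=1), encoding)

    def test_rate_one_complements_grammar_block_only(self, encoding):
        noisy = inject_noise(encoding, 1.0, seed=1)
        assert np.array_equal(noisy[:, :6], encoding[:, :6])
        assert np.array_equal(noisy[:, 6:], 1 - encoding[:, 6:])

    def test_flip_fraction_within_binomial_bound(self, encoding):
        rate = 0.2
        noisy = inject_noise(encoding, rate, seed=7)
        frac = (noisy[:, 6:] != encoding[:, 6:]).mean()
        bound = 3 * np.sqrt(rate * (1 - rate) / encoding[:, 6:].size)
        assert abs(frac - rate) < bound

    def test_invalid_rate(self, encoding):
        with pytest.raises(ValueError):
            inject_noise(encoding, 1.5, seed=0)


class TestStructureF1:
    def test_identical_structures(self):
        assert structure_f1("(...)", "(...)") == 1.0

    def test_disjoint_pairs(self):
        assert structure_f1("(...)....", "....(...)") == 0.0

    def test_partial_overlap(self):
        # true pairs {(0,8),(1,7)}; predicted {(0,8)} -> P=1, R=0.5
        assert structure_f1("((.....))", "(.......)") == pytest.approx(2 / 3)


class TestIdentity:
    def test_identical(self):
        assert sequence_identity("gaauc", "gaauc") == 1.0

    def test_disjoint(self):
        assert sequence_identity("aaaa", "cccc") == 0.0

    def test_single_mismatch(self):
        assert sequence_identity("gaauc", "gaaac") == pytest.approx(0.8)

    def test_stats_bundle(self):
        stats = identity_stats(["gaauc", "gaaac"], reference_set=["gaauc"])
        assert stats["median_pairwise"] == pytest.approx(0.8)
        assert stats["max_identity"].tolist() == [1.0, 0.8]

    def test_strip_padding(self):
        assert strip_padding("ga-ucxx", "(...)..") == ("gauc", "(..)")
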