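"""VAE architecture, loss decomposition, gradients and training."""

import numpy as np
import pytest

from rnagvae.codec import N_COLUMNS
from rnagvae.vae import (
    GrammarVAE,
    ModelConfig,
    build_model,
    decode_latent,
    encode_latent,
    evaluate,
    loss,
    loss_and_grads,
    predict_activity,
    reconstruct,
    sample_prior,
    train,
)


def tiny_config(**kw):
    base = dict(encoder_widths=(12, 9, 6), latent_dim=3, seed=3)
    base.update(kw)
    return ModelConfig(**base)


def one_hot_batch(n, L, seed=0, with_grammar=True):
    rng = np.random.default_rng(seed)
    X = np.zeros((n, L, N_COLUMNS))
    for s in range(n):
        for r in range(L):
            X[s, r, rng.integers(6)] = 1.0
    if with_grammar:
        X[:, :, 6:] = rng.random((n, L, 11)) < 0.3
    return X.reshape(n, -1)


class TestArchitecture:
    def test_input_output_dimension(self):
        model = build_model(ModelConfig(scale_factor=1 / 64), L=50)
        assert model.input_dim == 850
        z = encode_latent(model, np.zeros((50, N_COLUMNS)))
        assert z.mu.shape == (8,)
        assert (z.sigma > 0).all()

    def test_decoder_output_ranges(self):
        model = build_model(tiny_config(), L=7)
        out = decode_latent(model, np.ones(3))
        assert out.shape == (7, N_COLUMNS)
        assert np.allclose(out[:, :6].sum(axis=1), 1.0)  # row-wise softmax
        assert ((out[:, 6:] > 0) & (out[:, 6:] < 1)).all()  # sigmoids

    def test_scale_factor_shrinks_widths(self):
        assert ModelConfig(scale_factor=1 / 16).hidden_widths()[0] == 256
        assert ModelConfig(scale_factor=1 / 64).hidden_widths() == (64, 32, 8)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            build_model(ModelConfig(latent_dim=0), L=4)

    def test_checkpoint_roundtrip(self, tmp_path):
        model = build_model(tiny_config(with_activity=True), L=4)
        path = tmp_path / "model.npz"
        model.save(path)
        clone = GrammarVAE.load(path)
        z = np.array([0.3, -0.2, 0.8])
        assert np.array_equal(decode_latent(clone, z), decode_latent(model, z))
        assert predict_activity(clone, z) == predict_activity(model, z)


class TestLoss:
    def test_perfect_reconstruction_limit(self):
        L = 4
        B = np.zeros((L, N_COLUMNS))
        B[:, 0] = 1.0
        B_hat = B.copy()
        B_hat[:, :6] = np.clip(B_hat[:, :6], 1e-15, 1 - 1e-15)
        B_hat[:, 6:] = np.clip(B_hat[:, 6:], 1e-15, 1 - 1e-15)
        bd = loss(B, B_hat, mu=np.zeros(3), sigma=np.ones(3))
        assert bd.rec_ce == pytest.approx(0.0, abs=1e-9)
        assert bd.rec_bc == pytest.approx(0.0, abs=1e-9)
        assert bd.kl == 0.0
        assert bd.total == pytest.approx(0.0, abs=1e-9)

    def test_uniform_nucleotide_prediction_costs_ln6(self):
        """Summed CE under a uniform 6-way prediction, scaled by 1/L,
        is exactly ln 6 whatever L is."""
        for L in (1, 5, 20):
            B = np.zeros((L, N_COLUMNS))
            B[:, 2] = 1.0
            B_hat = np.full((L, N_COLUMNS), 0.5)
            B_hat[:, :6] = 1.0 / 6.0
            bd = loss(B, B_hat, mu=np.zeros(2), sigma=np.ones(2))
            assert bd.rec_ce == pytest.approx(np.log(6), rel=1e-12)

    def test_kl_zero_iff_standard_normal(self):
        B = np.zeros((2, N_COLUMNS))
        B[:, 0] = 1
        B_hat = np.full_like(B, 0.5, dtype=float)
        at_prior = loss(B, B_hat, np.zeros(3), np.ones(3))
        assert at_prior.kl == 0.0
        shifted = loss(B, B_hat, np.full(3, 0.1), np.ones(3))
        assert shifted.kl > 0.0

    def test_lambda_zero_removes_posterior_dependence(self):
        B = np.zeros((2, N_COLUMNS))
        B[:, 0] = 1
        B_hat = np.full_like(B, 0.5, dtype=float)
        a = loss(B, B_hat, np.zeros(2), np.ones(2), lambda_kl=0.0)
        b = loss(B, B_hat, np.full(2, 3.0), np.full(2, 9.0), lambda_kl=0.0)
        assert a.total == b.total

    def test_activity_term(self):
        B = np.zeros((2, N_COLUMNS))
        B[:, 0] = 1
        B_hat = np.full_like(B, 0.5, dtype=float)
        bd = loss(B, B_hat, np.zeros(2), np.ones(2),
                  activity=0.2, predicted_activity=0.7)
        assert bd.activity_mse == pytest.approx(0.25)

    def test_sigma_must_be_positive(self):
        B = np.zeros((2, N_COLUMNS))
        B[:, 0] = 1
        with pytest.raises(ValueError):
            loss(B, B, np.zeros(2), np.zeros(2))


class TestGradients:
    def test_finite_difference_agreement(self):
        """Analytic backprop matches central finite differences to 1e-4
        relative on a tiny model with an activity head."""
        cfg = tiny_config(with_activity=True, activity_head_widths=(4,))
        L = 4
        model = build_model(cfg, L)
        rng = np.random.default_rng(0)
        X = one_hot_batch(3, L, seed=0)
        acts = rng.random(3)
        eps = rng.standard_normal((3, cfg.latent_dim))
        _, grads = loss_and_grads(model, X, eps, acts)
        h = 1e-6
        worst = 0.0
        for name, p in model.params.items():
            for _ in range(5):
                ix = tuple(rng.integers(0, s) for s in p.shape)
                orig = p[ix]
                p[ix] = orig + h
                up, _ = loss_and_grads(model, X, eps, acts)
                p[ix] = orig - h
                dn, _ = loss_and_grads(model, X, eps, acts)
                p[ix] = orig
                num = (up.total - dn.total) / (2 * h)
                ana = grads[name][ix]
                rel = abs(num - ana) / max(1e-6, abs(num), abs(ana))
                worst = max(worst, rel)
        assert worst < 1e-4


class TestTraining:
    def test_loss_decreases(self, small_family):
        dataset, _ = small_family
        cfg = ModelConfig(scale_factor=1 / 64, epochs=30, seed=7)
        model, log = train(dataset.matrices, cfg)
        assert log.train_total[-1] < log.train_total[0]
        assert len(log.epochs) == 30

    def test_zero_epochs_returns_untrained_model(self):
        X = one_hot_batch(4, 5, seed=1)
        cfg = tiny_config(epochs=0)
        model, log = train(X, cfg)
        fresh = build_model(cfg, 5)
        assert all(
            np.array_equal(model.params[k], fresh.params[k]) for k in model.params
        )
        assert log.epochs == []

    def test_training_is_reproducible(self):
        X = one_hot_batch(6, 5, seed=2)
        cfg = tiny_config(epochs=10)
        m1, log1 = train(X, cfg)
        m2, log2 = train(X, cfg)
        assert log1.train_total == log2.train_total
        assert all(np.array_equal(m1.params[k], m2.params[k]) for k in m1.params)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train(np.zeros((0, 85)), tiny_config())

    def test_activity_predictions_bounded(self):
        X = one_hot_batch(6, 5, seed=4)
        cfg = tiny_config(epochs=5, with_activity=True)
        acts = np.linspace(0, 1, 6)
        model, _ = train(X, cfg, activities=acts)
        for row in X:
            z = encode_latent(model, row.reshape(5, N_COLUMNS)).mu
            assert 0.0 <= predict_activity(model, z) <= 1.0

    def test_reconstruct_is_deterministic(self):
        X = one_hot_batch(4, 5, seed=5)
        model, _ = train(X, tiny_config(epochs=5))
        B = X[0].reshape(5, N_COLUMNS)
        assert np.array_equal(reconstruct(model, B), reconstruct(model, B))


class TestPrior:
    def test_shape_and_moments(self):
        Z = sample_prior(1000, seed=9)
        assert Z.shape == (1000, 8)
        assert np.abs(Z.mean(axis=0)).max() < 4 / np.sqrt(1000)

    def test_seed_reproducibility(self):
        assert np.array_equal(sample_prior(10, seed=3), sample_prior(10, seed=3))
        assert not np.array_equal(sample_prior(10, seed=3), sample_prior(10, seed=4))

    def test_n_must_be_positive(self):
        with pytest.raises(ValueError):
            sample_prior(0, seed=1)
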