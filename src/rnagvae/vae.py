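"""Variational autoencoder over flattened L x 17 grammar encodings.

A three-hidden-layer fully connected encoder maps the flattened matrix to
the mean and log-variance of a diagonal Gaussian posterior over an
8-dimensional latent space; a mirrored decoder maps a latent vector back
to an L x 17 reconstruction in which the six nucleotide columns of each
row pass through a row-wise softmax and the eleven grammar columns
through elementwise sigmoids, so every reconstructed value lies in
[0, 1].

The training objective is

    loss = alpha * CE(Bn, Bn_hat) + beta * BC(Bg, Bg_hat)
           + lambda * KL(q(Z|B) || N(0, I))  [+ w * MSE(activity)]

with alpha = 1/L (mean per-position cross-entropy over the one-hot
block) and beta = 1/(L*11) (mean binary cross-entropy over the grammar
block).  An optional activity head — a small MLP from the latent vector
to a sigmoid scalar — adds a mean-squared-error term for per-sequence
activities normalized to [0, 1].

The network, its backpropagation and the Adam optimizer are implemented
directly in NumPy; the analytic gradients are validated against finite
differences in the test suite.  Training is deterministic for a fixed
seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .codec import N_COLUMNS, N_NUC, N_GRAMMAR

_EPS = 1e-12  # log/denominator guard


@dataclass
class ModelConfig:
    """Hyperparameters of the VAE.

    ``scale_factor`` shrinks every hidden width (e.g. 1/64 for the
    reduced models); ``encoder_widths`` is the full-size reference.  The
    decoder always mirrors the encoder.
    """

    encoder_widths: tuple[int, ...] = (4096, 2048, 516)
    latent_dim: int = 8
    lambda_kl: float = 0.001
    learning_rate: float = 0.001
    epochs: int = 2000
    batch_size: int = 100
    seed: int = 0
    with_activity: bool = False
    activity_weight: float = 1.0
    activity_head_widths: tuple[int, ...] = (32,)
    scale_factor: float = 1.0

    def hidden_widths(self) -> tuple[int, ...]:
        return tuple(max(1, round(w * self.scale_factor)) for w in self.encoder_widths)

    def validate(self) -> None:
        if any(w < 1 for w in self.encoder_widths) or self.latent_dim < 1:
            raise ValueError("layer widths and latent_dim must be >= 1")
        if self.lambda_kl < 0:
            raise ValueError("lambda_kl must be >= 0")


@dataclass
class LatentPoint:
    """Posterior parameters (and representative point) for one input."""

    z: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray


@dataclass
class LossBreakdown:
    """The decomposed objective; ``total`` includes the KL weight."""

    rec_ce: float
    rec_bc: float
    kl: float
    activity_mse: float = 0.0
    total: float = 0.0


@dataclass
class TrainingLog:
    """Per-epoch learning curves."""

    epochs: list[int] = field(default_factory=list)
    train_total: list[float] = field(default_factory=list)
    train_ce: list[float] = field(default_factory=list)
    train_bc: list[float] = field(default_factory=list)
    train_kl: list[float] = field(default_factory=list)
    train_activity: list[float] = field(default_factory=list)
    test_total: list[float] = field(default_factory=list)

    def to_tsv(self) -> str:
        header = "epoch\ttrain_loss\ttest_loss\tce\tbc\tkl\tactivity"
        lines = [header]
        for n, e in enumerate(self.epochs):
            test = self.test_total[n] if self.test_total else float("nan")
            lines.append(
                f"{e}\t{self.train_total[n]:.6g}\t{test:.6g}\t"
                f"{self.train_ce[n]:.6g}\t{self.train_bc[n]:.6g}\t"
                f"{self.train_kl[n]:.6g}\t{self.train_activity[n]:.6g}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------

class GrammarVAE:
    """Weight container plus forward passes.  Use :func:`build_model`."""

    def __init__(self, cfg: ModelConfig, L: int):
        cfg.validate()
        self.cfg = cfg
        self.L = L
        self.input_dim = L * N_COLUMNS
        rng = np.random.default_rng(cfg.seed)
        widths = cfg.hidden_widths()
        d = cfg.latent_dim
        self.params: dict[str, np.ndarray] = {}

        def linear(name: str, fan_in: int, fan_out: int) -> None:
            scale = np.sqrt(2.0 / fan_in)
            self.params[f"{name}_W"] = rng.normal(0.0, scale, (fan_in, fan_out))
            self.params[f"{name}_b"] = np.zeros(fan_out)

        prev = self.input_dim
        for n, w in enumerate(widths):
            linear(f"enc{n}", prev, w)
            prev = w
        linear("mu", prev, d)
        linear("logvar", prev, d)
        # Start the posterior nearly deterministic: with the small KL
        # weights typical here the variance re-inflates during training,
        # while early reconstruction gradients are not drowned in
        # reparameterization noise.
        self.params["logvar_b"][:] = -8.0
        prev = d
        for n, w in enumerate(reversed(widths)):
            linear(f"dec{n}", prev, w)
            prev = w
        linear("out", prev, self.input_dim)
        if cfg.with_activity:
            prev = d
            for n, w in enumerate(cfg.activity_head_widths):
                linear(f"act{n}", prev, w)
                prev = w
            linear("act_out", prev, 1)
        self._n_hidden = len(widths)

    # -- forward passes ---------------------------------------------------

    def encode(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, list]:
        """Posterior parameters (mu, logvar) of a batch; returns the
        ReLU cache for backprop."""
        cache = []
        h = X
        for n in range(self._n_hidden):
            a = h @ self.params[f"enc{n}_W"] + self.params[f"enc{n}_b"]
            cache.append((h, a))
            h = np.maximum(a, 0.0)
        mu = h @ self.params["mu_W"] + self.params["mu_b"]
        logvar = h @ self.params["logvar_W"] + self.params["logvar_b"]
        cache.append((h, None))
        return mu, logvar, cache

    def decode(self, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray, list]:
        """Reconstruction probabilities (Bn softmax, Bg sigmoid) of a
        batch of latent vectors; returns the cache for backprop."""
        cache = []
        h = Z
        for n in range(self._n_hidden):
            a = h @ self.params[f"dec{n}_W"] + self.params[f"dec{n}_b"]
            cache.append((h, a))
            h = np.maximum(a, 0.0)
        logits = h @ self.params["out_W"] + self.params["out_b"]
        cache.append((h, None))
        lg = logits.reshape(-1, self.L, N_COLUMNS)
        ln = lg[:, :, :N_NUC]
        ln = ln - ln.max(axis=2, keepdims=True)
        en = np.exp(ln)
        p_nuc = en / en.sum(axis=2, keepdims=True)
        p_gram = 1.0 / (1.0 + np.exp(-lg[:, :, N_NUC:]))
        return p_nuc, p_gram, cache

    def activity_forward(self, Z: np.ndarray) -> tuple[np.ndarray, list]:
        """Sigmoid activity prediction in [0, 1] for a batch of latents."""
        if not self.cfg.with_activity:
            raise ValueError("model was built without an activity head")
        cache = []
        h = Z
        for n in range(len(self.cfg.activity_head_widths)):
            a = h @ self.params[f"act{n}_W"] + self.params[f"act{n}_b"]
            cache.append((h, a))
            h = np.maximum(a, 0.0)
        a_out = h @ self.params["act_out_W"] + self.params["act_out_b"]
        pred = 1.0 / (1.0 + np.exp(-a_out[:, 0]))
        cache.append((h, None))
        return pred, cache

    # -- persistence ------------------------------------------------------

    def save(self, path: str) -> None:
        """Single-file checkpoint with the config embedded."""
        meta = asdict(self.cfg)
        meta["L"] = self.L
        np.savez(path, __config__=json.dumps(meta), **self.params)

    @classmethod
    def load(cls, path: str) -> "GrammarVAE":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__config__"]))
        L = meta.pop("L")
        for key in ("encoder_widths", "activity_head_widths"):
            meta[key] = tuple(meta[key])
        model = cls(ModelConfig(**meta), L)
        for name in model.params:
            model.params[name] = data[name]
        return model


def build_model(cfg: ModelConfig, L: int) -> GrammarVAE:
    """Instantiate a VAE for flattened matrices of ``L`` rows."""
    return GrammarVAE(cfg, L)


def init_output_bias(model: GrammarVAE, X: np.ndarray) -> None:
    """Set the decoder's output bias to the data's marginal log-odds.

    The decoder then reproduces the dataset marginals from step one and
    gradient descent is spent on per-item differences rather than on
    re-deriving the family consensus.  Called by :func:`train`.
    """
    mean = np.asarray(X, dtype=np.float64).mean(axis=0).reshape(model.L, N_COLUMNS)
    bn = np.clip(mean[:, :N_NUC], 1e-3, 1.0)
    bg = np.clip(mean[:, N_NUC:], 1e-3, 1.0 - 1e-3)
    model.params["out_b"][:] = np.concatenate(
        [np.log(bn), np.log(bg / (1.0 - bg))], axis=1
    ).reshape(-1)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def loss(
    B: np.ndarray,
    B_hat: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
    lambda_kl: float = 0.001,
    activity: Optional[float] = None,
    predicted_activity: Optional[float] = None,
    activity_weight: float = 1.0,
) -> LossBreakdown:
    """Decomposed objective for a single (B, reconstruction) pair.

    ``rec_ce`` is the summed categorical cross-entropy of the one-hot
    nucleotide rows scaled by 1/L; ``rec_bc`` the summed binary
    cross-entropy of the grammar cells scaled by 1/(L*11); ``kl`` the
    closed-form divergence of the diagonal Gaussian posterior from the
    standard normal.  ``total`` applies the KL weight ``lambda_kl``.
    """
    B = np.asarray(B, dtype=np.float64)
    B_hat = np.asarray(B_hat, dtype=np.float64)
    if B.shape != B_hat.shape or B.shape[1] != N_COLUMNS:
        raise ValueError(f"shape mismatch: {B.shape} vs {B_hat.shape}")
    mu = np.asarray(mu, dtype=np.float64)
    sigma = np.asarray(sigma, dtype=np.float64)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    L = B.shape[0]
    p_nuc = np.clip(B_hat[:, :N_NUC], _EPS, 1.0)
    rec_ce = float(-(B[:, :N_NUC] * np.log(p_nuc)).sum() / L)
    p_g = np.clip(B_hat[:, N_NUC:], _EPS, 1.0 - _EPS)
    b_g = B[:, N_NUC:]
    rec_bc = float(
        -(b_g * np.log(p_g) + (1.0 - b_g) * np.log(1.0 - p_g)).sum() / (L * N_GRAMMAR)
    )
    kl = float(0.5 * np.sum(mu**2 + sigma**2 - 1.0 - 2.0 * np.log(sigma)))
    out = LossBreakdown(rec_ce=rec_ce, rec_bc=rec_bc, kl=kl)
    out.total = rec_ce + rec_bc + lambda_kl * kl
    if activity is not None and predicted_activity is not None:
        out.activity_mse = float((predicted_activity - activity) ** 2)
        out.total += activity_weight * out.activity_mse
    return out


# ---------------------------------------------------------------------------
# Backpropagation
# ---------------------------------------------------------------------------

def loss_and_grads(
    model: GrammarVAE,
    X: np.ndarray,
    eps: np.ndarray,
    activities: Optional[np.ndarray] = None,
) -> tuple[LossBreakdown, dict[str, np.ndarray]]:
    """Batch-mean loss and analytic gradients for fixed posterior noise.

    ``eps`` is the reparameterization draw (z = mu + sigma * eps); fixing
    it makes the function deterministic, which both the optimizer step
    and the finite-difference gradient check rely on.
    """
    cfg = model.cfg
    n, L = X.shape[0], model.L
    grads = {name: np.zeros_like(p) for name, p in model.params.items()}

    mu, logvar, enc_cache = model.encode(X)
    sigma = np.exp(0.5 * logvar)
    Z = mu + sigma * eps
    p_nuc, p_gram, dec_cache = model.decode(Z)

    Bn = X.reshape(n, L, N_COLUMNS)[:, :, :N_NUC]
    Bg = X.reshape(n, L, N_COLUMNS)[:, :, N_NUC:]

    pn = np.clip(p_nuc, _EPS, 1.0)
    ce = -(Bn * np.log(pn)).sum(axis=(1, 2)) / L
    pg = np.clip(p_gram, _EPS, 1.0 - _EPS)
    bc = -(Bg * np.log(pg) + (1 - Bg) * np.log(1 - pg)).sum(axis=(1, 2)) / (
        L * N_GRAMMAR
    )
    kl = 0.5 * (mu**2 + np.exp(logvar) - 1.0 - logvar).sum(axis=1)

    total = ce.mean() + bc.mean() + cfg.lambda_kl * kl.mean()
    breakdown = LossBreakdown(
        rec_ce=float(ce.mean()), rec_bc=float(bc.mean()), kl=float(kl.mean())
    )

    # Gradient at the decoder logits (softmax-CE and sigmoid-BC shortcuts).
    dlogits = np.empty((n, L, N_COLUMNS))
    dlogits[:, :, :N_NUC] = (p_nuc - Bn) / (L * n)
    dlogits[:, :, N_NUC:] = (p_gram - Bg) / (L * N_GRAMMAR * n)
    dh = dlogits.reshape(n, -1)

    # Output linear layer, then the mirrored hidden stack.
    h_last = dec_cache[-1][0]
    grads["out_W"] = h_last.T @ dh
    grads["out_b"] = dh.sum(axis=0)
    dh = dh @ model.params["out_W"].T
    for layer in range(model._n_hidden - 1, -1, -1):
        h_in, a = dec_cache[layer]
        dh = dh * (a > 0)
        grads[f"dec{layer}_W"] = h_in.T @ dh
        grads[f"dec{layer}_b"] = dh.sum(axis=0)
        dh = dh @ model.params[f"dec{layer}_W"].T
    dZ = dh

    # Optional activity head.
    if activities is not None:
        if not cfg.with_activity:
            raise ValueError("activities given but model has no activity head")
        pred, act_cache = model.activity_forward(Z)
        mse = (pred - activities) ** 2
        breakdown.activity_mse = float(mse.mean())
        total = total + cfg.activity_weight * mse.mean()
        da = (
            cfg.activity_weight * 2.0 * (pred - activities) * pred * (1.0 - pred) / n
        )[:, None]
        h_last = act_cache[-1][0]
        grads["act_out_W"] = h_last.T @ da
        grads["act_out_b"] = da.sum(axis=0)
        da = da @ model.params["act_out_W"].T
        for layer in range(len(cfg.activity_head_widths) - 1, -1, -1):
            h_in, a = act_cache[layer]
            da = da * (a > 0)
            grads[f"act{layer}_W"] = h_in.T @ da
            grads[f"act{layer}_b"] = da.sum(axis=0)
            da = da @ model.params[f"act{layer}_W"].T
        dZ = dZ + da

    # Through the reparameterization into the posterior parameters.
    dmu = dZ + cfg.lambda_kl * mu / n
    dlogvar = dZ * eps * 0.5 * sigma + cfg.lambda_kl * 0.5 * (np.exp(logvar) - 1.0) / n

    h_last = enc_cache[-1][0]
    grads["mu_W"] = h_last.T @ dmu
    grads["mu_b"] = dmu.sum(axis=0)
    grads["logvar_W"] = h_last.T @ dlogvar
    grads["logvar_b"] = dlogvar.sum(axis=0)
    dh = dmu @ model.params["mu_W"].T + dlogvar @ model.params["logvar_W"].T
    for layer in range(model._n_hidden - 1, -1, -1):
        h_in, a = enc_cache[layer]
        dh = dh * (a > 0)
        grads[f"enc{layer}_W"] = h_in.T @ dh
        grads[f"enc{layer}_b"] = dh.sum(axis=0)
        dh = dh @ model.params[f"enc{layer}_W"].T

    breakdown.total = float(total)
    return breakdown, grads


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k in params:
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )


def _as_batch(dataset) -> np.ndarray:
    X = np.asarray(dataset, dtype=np.float64)
    if X.ndim == 3:
        if X.shape[2] != N_COLUMNS:
            raise ValueError("matrices must have 17 columns")
        X = X.reshape(X.shape[0], -1)
    if X.ndim != 2:
        raise ValueError("dataset must be (n, L, 17) matrices or flat vectors")
    return X


def evaluate(
    model: GrammarVAE, X: np.ndarray, activities: Optional[np.ndarray] = None
) -> LossBreakdown:
    """Deterministic batch-mean loss (posterior mean, no sampling)."""
    X = _as_batch(X)
    bd, _ = loss_and_grads(model, X, eps=np.zeros((X.shape[0], model.cfg.latent_dim)),
                           activities=activities)
    return bd


def train(
    dataset,
    cfg: ModelConfig,
    L: Optional[int] = None,
    activities: Optional[Sequence[float]] = None,
    test_fraction: Optional[float] = None,
) -> tuple[GrammarVAE, TrainingLog]:
    """Seeded minibatch Adam training with per-epoch learning curves.

    ``dataset`` is an array of equal-length encoded matrices (n, L, 17)
    or flattened vectors.  With ``test_fraction`` a seeded random split
    is held out and its deterministic loss recorded per epoch.
    """
    X = _as_batch(dataset)
    if X.shape[0] == 0:
        raise ValueError("empty dataset")
    if L is None:
        if X.shape[1] % N_COLUMNS:
            raise ValueError("flattened length not divisible by 17 (mixed L?)")
        L = X.shape[1] // N_COLUMNS
    if X.shape[1] != L * N_COLUMNS:
        raise ValueError("dataset length inconsistent with L")
    acts = None if activities is None else np.asarray(activities, dtype=np.float64)
    if acts is not None and (acts.min() < 0 or acts.max() > 1):
        raise ValueError("activities must be normalized to [0, 1]")

    model = build_model(cfg, L)
    rng = np.random.default_rng(cfg.seed + 1)

    test_X = test_acts = None
    if test_fraction:
        n_test = int(round(X.shape[0] * test_fraction))
        perm = rng.permutation(X.shape[0])
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        test_X = X[test_idx]
        X = X[train_idx]
        if acts is not None:
            test_acts = acts[test_idx]
            acts = acts[train_idx]

    if cfg.epochs > 0:
        init_output_bias(model, X)
    opt = _Adam(model.params, cfg.learning_rate)
    log = TrainingLog()
    n = X.shape[0]
    bs = min(cfg.batch_size, n)
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        sums = np.zeros(5)  # total, ce, bc, kl, act (item-weighted)
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            eps = rng.standard_normal((idx.size, cfg.latent_dim))
            bd, grads = loss_and_grads(
                model, X[idx], eps, None if acts is None else acts[idx]
            )
            opt.step(model.params, grads)
            sums += idx.size * np.array(
                [bd.total, bd.rec_ce, bd.rec_bc, bd.kl, bd.activity_mse]
            )
        sums /= n
        log.epochs.append(epoch)
        log.train_total.append(sums[0])
        log.train_ce.append(sums[1])
        log.train_bc.append(sums[2])
        log.train_kl.append(sums[3])
        log.train_activity.append(sums[4])
        if test_X is not None and len(test_X):
            log.test_total.append(evaluate(model, test_X, test_acts).total)
    return model, log


# ---------------------------------------------------------------------------
# Latent-space operations
# ---------------------------------------------------------------------------

def encode_latent(model: GrammarVAE, B: np.ndarray) -> LatentPoint:
    """Posterior parameters of one encoded matrix; ``z`` is the mean
    (sampling happens only during training)."""
    X = _as_batch(B[None] if np.asarray(B).ndim == 2 else B)
    mu, logvar, _ = model.encode(X)
    sigma = np.exp(0.5 * logvar)
    return LatentPoint(z=mu[0], mu=mu[0], sigma=sigma[0])


def decode_latent(model: GrammarVAE, z: np.ndarray) -> np.ndarray:
    """Reconstructed L x 17 matrix (entries in [0, 1]) for one latent
    vector."""
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    if z.shape[1] != model.cfg.latent_dim:
        raise ValueError(f"latent vector must have {model.cfg.latent_dim} dims")
    p_nuc, p_gram, _ = model.decode(z)
    return np.concatenate([p_nuc[0], p_gram[0]], axis=1)


def reconstruct(model: GrammarVAE, B: np.ndarray) -> np.ndarray:
    """Deterministic round trip through the posterior mean."""
    return decode_latent(model, encode_latent(model, B).mu)


def predict_activity(model: GrammarVAE, z: np.ndarray) -> float:
    """Activity-head prediction in [0, 1] for one latent vector."""
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    pred, _ = model.activity_forward(z)
    return float(pred[0])


def sample_prior(n: int, seed: int, latent_dim: int = 8) -> np.ndarray:
    """``n`` standard-normal latent vectors, reproducible by seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return np.random.default_rng(seed).standard_normal((n, latent_dim))
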