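"""Conditional variational autoencoder over methylation beta values.

The encoder maps an individual sample concatenated with its two-hot
(species, tissue) label to the mean mu and log-variance sigma of a diagonal
Gaussian posterior over a Z-dimensional latent space.  The decoder maps a
latent draw, again concatenated with the label, back to per-probe logits;
beta values are obtained through a sigmoid.  Training minimizes

    L = BCE(X, sigmoid(logits))  +  1/2 sum_j [exp(sigma_j) + mu_j^2 - 1 - sigma_j]

i.e. the negative evidence lower bound with a Bernoulli-style reconstruction
likelihood evaluated at continuous targets, the KL term taken against the
standard normal prior.  The latent draw uses the reparameterization
z = mu + exp(sigma/2) * eps with eps ~ N(0, I), one Monte-Carlo draw per
sample per step by default.

Everything (initialization, shuffling, latent draws) is driven by explicit
seeds; identical seeds reproduce training bit-exactly.  The network is plain
NumPy with hand-derived gradients; a finite-difference check in the test
suite guards the backward pass.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .data import ConditionLabels, SampleMatrix, encode_condition_labels

_ACT = {
    "tanh": (np.tanh, lambda h: 1.0 - h * h),
    "relu": (lambda x: np.maximum(x, 0.0), lambda h: (h > 0).astype(float)),
    "sigmoid": (lambda x: 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500))),
                lambda h: h * (1.0 - h)),
    "elu": (lambda x: np.where(x > 0, x, np.expm1(np.minimum(x, 0.0))),
            lambda h: np.where(h > 0, 1.0, h + 1.0)),
}


@dataclass
class Hyperparameters:
    """Architecture and optimization settings subject to grid search.

    ``hidden_dims`` is given in encoder order; the decoder mirrors it.
    ``optimizer_epsilon`` is the Adam epsilon.  ``mc_samples`` is the number
    of Monte-Carlo latent draws per training step (L; default 1).
    """

    hidden_dims: tuple = (1024, 512)
    activation: str = "tanh"
    latent_dim: int = 8
    learning_rate: float = 1e-3
    optimizer_epsilon: float = 1e-4
    epochs: int = 200
    batch_size: int = 64
    mc_samples: int = 1

    def __post_init__(self) -> None:
        self.hidden_dims = tuple(int(d) for d in self.hidden_dims)
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.mc_samples < 1:
            raise ValueError("mc_samples must be >= 1")
        if self.activation not in _ACT:
            raise ValueError(f"unknown activation {self.activation!r}")
        if any(d < 1 for d in self.hidden_dims):
            raise ValueError("hidden dims must be positive")

    @property
    def n_hidden_layers(self) -> int:
        return len(self.hidden_dims)


@dataclass
class LossBreakdown:
    recon: float
    kl: float

    @property
    def total(self) -> float:
        return self.recon + self.kl


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class CVAEModel:
    """Encoder/decoder parameters plus the label vocabularies they were built for.

    Parameters live in ``self.params``, a flat list of arrays in a fixed
    order: encoder hidden layers (W, b)..., mu head (W, b), sigma head (W, b),
    decoder hidden layers (W, b)..., output head (W, b).
    """

    def __init__(self, hyper: Hyperparameters, n_probes: int, vocab: ConditionLabels,
                 seed: int):
        self.hyper = hyper
        self.n_probes = int(n_probes)
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        self.vocab = ConditionLabels([], [], list(vocab.species_vocab),
                                     list(vocab.tissue_vocab))
        self.seed = int(seed)
        L = vocab.n_species + vocab.n_tissues
        Z = hyper.latent_dim
        rng = np.random.default_rng(seed)
        self.params: list[np.ndarray] = []
        widths = [self.n_probes + L, *hyper.hidden_dims]
        self._n_enc = len(hyper.hidden_dims)
        for a, b in zip(widths[:-1], widths[1:]):
            self.params += [_glorot(rng, a, b), np.zeros(b)]
        last = widths[-1]
        self.params += [_glorot(rng, last, Z), np.zeros(Z)]   # mu head
        self.params += [_glorot(rng, last, Z), np.zeros(Z)]   # sigma head
        dwidths = [Z + L, *reversed(hyper.hidden_dims)]
        for a, b in zip(dwidths[:-1], dwidths[1:]):
            self.params += [_glorot(rng, a, b), np.zeros(b)]
        self.params += [_glorot(rng, dwidths[-1], self.n_probes), np.zeros(self.n_probes)]

    # -- parameter bookkeeping ------------------------------------------------
    @property
    def latent_dim(self) -> int:
        return self.hyper.latent_dim

    def _split(self):
        ne = self._n_enc
        enc = self.params[: 2 * ne]
        w_mu, b_mu, w_sig, b_sig = self.params[2 * ne: 2 * ne + 4]
        dec = self.params[2 * ne + 4: 4 * ne + 4]
        w_out, b_out = self.params[4 * ne + 4:]
        return enc, (w_mu, b_mu, w_sig, b_sig), dec, (w_out, b_out)

    # -- forward passes -------------------------------------------------------
    def encode(self, X: np.ndarray, Y: np.ndarray):
        """Posterior parameters (mu, sigma) for a batch; sigma is log-variance."""
        act, _ = _ACT[self.hyper.activation]
        enc, (w_mu, b_mu, w_sig, b_sig), _, _ = self._split()
        h = np.concatenate([X, Y], axis=1)
        for w, b in zip(enc[0::2], enc[1::2]):
            h = act(h @ w + b)
        return h @ w_mu + b_mu, h @ w_sig + b_sig

    def decode_logits(self, Z: np.ndarray, Y: np.ndarray) -> np.ndarray:
        act, _ = _ACT[self.hyper.activation]
        _, _, dec, (w_out, b_out) = self._split()
        h = np.concatenate([Z, Y], axis=1)
        for w, b in zip(dec[0::2], dec[1::2]):
            h = act(h @ w + b)
        return h @ w_out + b_out

    def decode(self, Z: np.ndarray, Y: np.ndarray) -> np.ndarray:
        """Decoded beta values: sigmoid of the output logits, in (0, 1)."""
        return _sigmoid(self.decode_logits(Z, Y))

    # -- serialization --------------------------------------------------------
    def save(self, path) -> None:
        header = json.dumps({
            "hyper": asdict(self.hyper),
            "n_probes": self.n_probes,
            "species_vocab": self.vocab.species_vocab,
            "tissue_vocab": self.vocab.tissue_vocab,
            "seed": self.seed,
        })
        np.savez(path, header=np.frombuffer(header.encode(), dtype=np.uint8),
                 **{f"p{i}": p for i, p in enumerate(self.params)})

    @classmethod
    def load(cls, path) -> "CVAEModel":
        with np.load(path) as archive:
            header = json.loads(bytes(archive["header"]).decode())
            hyper = Hyperparameters(**{**header["hyper"],
                                       "hidden_dims": tuple(header["hyper"]["hidden_dims"])})
            vocab = ConditionLabels([], [], header["species_vocab"], header["tissue_vocab"])
            model = cls(hyper, header["n_probes"], vocab, header["seed"])
            model.params = [archive[f"p{i}"] for i in range(len(model.params))]
        return model

    def check_matrix(self, matrix: SampleMatrix) -> None:
        if matrix.n_probes != self.n_probes:
            raise ValueError(
                f"matrix has {matrix.n_probes} probes but model expects {self.n_probes}")


def build_model(hyper: Hyperparameters, n_probes: int, vocab: ConditionLabels,
                seed: int) -> CVAEModel:
    """Deterministically initialize a model (Glorot-uniform weights, zero biases)."""
    return CVAEModel(hyper, n_probes, vocab, seed)


# ---------------------------------------------------------------------------
# Loss pieces
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _softplus(x: np.ndarray) -> np.ndarray:
    # log(1 + exp(x)) without overflow
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


def reparameterize(mu: np.ndarray, sigma: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """z = mu + exp(sigma/2) * eps, elementwise; sigma holds log-variances."""
    mu, sigma, eps = (np.asarray(a, dtype=float) for a in (mu, sigma, eps))
    if not (mu.shape == sigma.shape == eps.shape):
        raise ValueError("mu, sigma, eps must share a shape")
    return mu + np.exp(sigma / 2.0) * eps

def kl_divergence_term(mu: np.ndarray, sigma: np.ndarray) -> float:
    """KL(N(mu, diag exp(sigma)) || N(0, I)) summed over latent dimensions.

    For batched inputs the per-sample KLs are averaged.
    """
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    per_sample = 0.5 * np.sum(np.exp(sigma) + mu ** 2 - 1.0 - sigma, axis=1)
    return float(per_sample.mean())

def reconstruction_term(X: np.ndarray, logits: np.ndarray) -> float:
    """Binary cross-entropy of sigmoid(logits) against continuous targets.

    Summed over probes, averaged over the batch, evaluated in logit form:
    BCE = softplus(logit) - x * logit, which never overflows.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    logits = np.atleast_2d(np.asarray(logits, dtype=float))
    per_sample = np.sum(_softplus(logits) - X * logits, axis=1)
    return float(per_sample.mean())


def training_loss(X: np.ndarray, logits: np.ndarray, mu: np.ndarray,
                  sigma: np.ndarray) -> LossBreakdown:
    return LossBreakdown(recon=reconstruction_term(X, logits),
                         kl=kl_divergence_term(mu, sigma))


# ---------------------------------------------------------------------------
# Backward pass
# ---------------------------------------------------------------------------

def loss_and_grads(model: CVAEModel, X: np.ndarray, Y: np.ndarray,
                   eps: np.ndarray) -> tuple[LossBreakdown, list[np.ndarray]]:
    """Training loss and its gradient w.r.t. every parameter array.

    ``eps`` has shape (L, batch, Z): one standard-normal draw per MC sample.
    The reconstruction term is averaged over the L draws; KL is computed once
    from the posterior parameters.  Deterministic given ``eps``.
    """
    act, dact = _ACT[model.hyper.activation]
    enc, (w_mu, b_mu, w_sig, b_sig), dec, (w_out, b_out) = model._split()
    X = np.atleast_2d(X)
    Y = np.atleast_2d(Y)
    B = X.shape[0]
    L = eps.shape[0]

    # encoder forward with cached activations
    enc_acts = [np.concatenate([X, Y], axis=1)]
    for w, b in zip(enc[0::2], enc[1::2]):
        enc_acts.append(act(enc_acts[-1] @ w + b))
    h_enc = enc_acts[-1]
    mu = h_enc @ w_mu + b_mu
    sig = h_enc @ w_sig + b_sig

    grads = [np.zeros_like(p) for p in model.params]
    ne = model._n_enc
    g_enc = grads[: 2 * ne]
    g_mu_w, g_mu_b, g_sig_w, g_sig_b = range(2 * ne, 2 * ne + 4)
    g_dec = grads[2 * ne + 4: 4 * ne + 4]
    g_out_w, g_out_b = 4 * ne + 4, 4 * ne + 5

    # KL: mean over batch of 1/2 sum(exp(sig) + mu^2 - 1 - sig)
    kl = float((0.5 * np.sum(np.exp(sig) + mu ** 2 - 1.0 - sig, axis=1)).mean())
    dmu = mu / B
    dsig = 0.5 * (np.exp(sig) - 1.0) / B

    recon_sum = 0.0
    half_exp = 0.5 * np.exp(sig / 2.0)
    for draw in range(L):
        z = mu + np.exp(sig / 2.0) * eps[draw]
        dec_acts = [np.concatenate([z, Y], axis=1)]
        for w, b in zip(dec[0::2], dec[1::2]):
            dec_acts.append(act(dec_acts[-1] @ w + b))
        logits = dec_acts[-1] @ w_out + b_out
        recon_sum += float(np.sum(_softplus(logits) - X * logits))

        dlogits = (_sigmoid(logits) - X) / (B * L)
        grads[g_out_w] += dec_acts[-1].T @ dlogits
        grads[g_out_b] += dlogits.sum(axis=0)
        g = dlogits @ w_out.T
        for li in range(len(dec) // 2 - 1, -1, -1):
            gpre = g * dact(dec_acts[li + 1])
            g_dec[2 * li] += dec_acts[li].T @ gpre
            g_dec[2 * li + 1] += gpre.sum(axis=0)
            g = gpre @ dec[2 * li].T
        dz = g[:, : model.latent_dim]
        dmu = dmu + dz
        dsig = dsig + dz * eps[draw] * half_exp

    recon = recon_sum / (B * L)

    grads[g_mu_w] = h_enc.T @ dmu
    grads[g_mu_b] = dmu.sum(axis=0)
    grads[g_sig_w] = h_enc.T @ dsig
    grads[g_sig_b] = dsig.sum(axis=0)
    g = dmu @ w_mu.T + dsig @ w_sig.T
    for li in range(len(enc) // 2 - 1, -1, -1):
        gpre = g * dact(enc_acts[li + 1])
        g_enc[2 * li] += enc_acts[li].T @ gpre
        g_enc[2 * li + 1] += gpre.sum(axis=0)
        g = gpre @ enc[2 * li].T

    return LossBreakdown(recon=recon, kl=kl), grads


class _Adam:
    def __init__(self, params, lr: float, eps: float, beta1=0.9, beta2=0.999):
        self.lr, self.eps, self.b1, self.b2 = lr, eps, beta1, beta2
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class LossTrace:
    recon: list = field(default_factory=list)
    kl: list = field(default_factory=list)

    @property
    def total(self) -> list:
        return [r + k for r, k in zip(self.recon, self.kl)]


def fit(model: CVAEModel, matrix: SampleMatrix, labels: ConditionLabels,
        seed: int) -> LossTrace:
    """Train in place with Adam; returns the per-epoch mean loss trace.

    Each step draws ``mc_samples`` fresh latent noise vectors per sample.
    Identical seeds give identical final weights.
    """
    model.check_matrix(matrix)
    if matrix.n_samples != labels.n_samples:
        raise ValueError("matrix and labels disagree on sample count")
    hp = model.hyper
    X_all = matrix.values
    Y_all = encode_condition_labels(model.vocab, labels.pairs())
    rng = np.random.default_rng(seed)
    opt = _Adam(model.params, hp.learning_rate, hp.optimizer_epsilon)
    trace = LossTrace()
    n = X_all.shape[0]
    for epoch in range(hp.epochs):
        order = rng.permutation(n)
        recon_sum = kl_sum = 0.0
        for start in range(0, n, hp.batch_size):
            idx = order[start:start + hp.batch_size]
            eps = rng.standard_normal((hp.mc_samples, len(idx), hp.latent_dim))
            loss, grads = loss_and_grads(model, X_all[idx], Y_all[idx], eps)
            if not np.isfinite(loss.total):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: "
                    f"recon={loss.recon!r} kl={loss.kl!r}")
            opt.step(model.params, grads)
            recon_sum += loss.recon * len(idx)
            kl_sum += loss.kl * len(idx)
        trace.recon.append(recon_sum / n)
        trace.kl.append(kl_sum / n)
    return trace


def grid_search_hyperparameters(grid, train_matrix: SampleMatrix,
                                train_labels: ConditionLabels,
                                val_means, seed: int):
    """Pick the grid point whose imputations best match validation combo means.

    For each hyperparameter combination a model is trained on the training
    individuals and used to impute every validation combination; the score is
    the mean sample-wise Pearson correlation against the validation
    combination means.  Ties (and NaN scores) resolve to the earliest grid
    point with the best finite score.

    Returns ``(best_hyper, table)`` where table is a list of
    ``(hyper, score, model)`` triples in grid order.
    """
    from .imputation import impute_combination_mean

    grid = list(grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    table = []
    for hyper in grid:
        model = build_model(hyper, train_matrix.n_probes, train_labels, seed)
        fit(model, train_matrix, train_labels, seed)
        rs = []
        for i, key in enumerate(val_means.keys):
            imp = impute_combination_mean(model, key, seed=seed * 1000 + i).values
            obs = val_means.values[i]
            if obs.std() == 0 or imp.std() == 0:
                continue
            rs.append(float(np.corrcoef(imp, obs)[0, 1]))
        score = float(np.mean(rs)) if rs else float("nan")
        table.append((hyper, score, model))
    finite = [(i, s) for i, (_, s, _) in enumerate(table) if np.isfinite(s)]
    if not finite:
        raise ValueError("no grid point produced a finite validation score")
    best_i = max(finite, key=lambda t: t[1])[0]
    return table[best_i][0], table
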