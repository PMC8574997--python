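"""SMILES variational autoencoder fingerprints.

SMILES strings are one-hot encoded over a corpus-derived character vocabulary
plus a reserved zero-pad token, at a fixed input length of 140.  The encoder
is three 1-D convolutions (9, 9 and 10 filters) with SELU activations feeding
a dense layer that parameterizes a diagonal Gaussian posterior (mu, log
sigma^2) over a 16- or 256-dimensional latent space.  The decoder repeats the
latent vector at every position through a stack of three GRU layers of hidden
width 501 and a softmax readout over the vocabulary.  The loss is an equally
weighted sum of binary cross-entropy (reconstruction) and the KL divergence
from the standard-normal prior; weights start from Xavier uniform draws.

The fingerprint of a molecule is the posterior mean mu — no sampling — so
fingerprints are deterministic given trained weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn
from .nn import Adam, PlateauHalving, Tensor, TrainingDivergedError, concat
from .rulefp import ConfigError, FingerprintMatrix

logger = logging.getLogger("fpbench.vae")

PAD_CHAR = ""  # the reserved zero-pad vocabulary slot (index 0)


@dataclass
class VAEConfig:
    max_len: int = 140
    latent_dim: int = 16
    conv_channels: tuple[int, ...] = (9, 9, 10)
    conv_kernels: tuple[int, ...] = (9, 9, 10)
    dense_hidden: int = 196
    gru_hidden: int = 501
    gru_layers: int = 3
    bce_weight: float = 0.5
    kl_weight: float = 0.5
    lr_init: float = 1e-3
    lr_floor: float = 1e-6
    epochs: int = 10
    folds: int = 5
    batch_size: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim not in (16, 256):
            raise ConfigError(f"latent_dim must be 16 or 256, got {self.latent_dim}")
        if not self.lr_floor < self.lr_init:
            raise ConfigError("lr_floor must be below lr_init")
        if len(self.conv_channels) != len(self.conv_kernels):
            raise ConfigError("conv_channels and conv_kernels must align")


class Vocabulary:
    """Ordered character set built from a training corpus, pad token at index 0."""

    def __init__(self, chars: Sequence[str]):
        self.chars: list[str] = [PAD_CHAR] + sorted(set(chars) - {PAD_CHAR})
        self.index = {c: i for i, c in enumerate(self.chars)}

    @classmethod
    def from_corpus(cls, corpus: Sequence[str]) -> "Vocabulary":
        return cls(sorted({c for s in corpus for c in s}))

    def __len__(self) -> int:
        return len(self.chars)

    def encode(self, smiles: str, max_len: int) -> np.ndarray:
        """Integer codes, zero-padded; unknown characters route to pad with a warning."""
        if len(smiles) > max_len:
            raise ValueError(f"SMILES length {len(smiles)} exceeds max_len {max_len}")
        codes = np.zeros(max_len, dtype=np.int64)
        for i, c in enumerate(smiles):
            code = self.index.get(c)
            if code is None:
                logger.warning("character %r not in vocabulary, mapped to pad slot", c)
                code = 0
            codes[i] = code
        return codes


def smiles_onehot(smiles: str, vocab: Vocabulary, max_len: int = 140) -> np.ndarray:
    """One-hot matrix (max_len x |vocab|); padding positions use the pad slot."""
    codes = vocab.encode(smiles, max_len)
    out = np.zeros((max_len, len(vocab)))
    out[np.arange(max_len), codes] = 1.0
    return out


# ---------------------------------------------------------------------------
# model


@dataclass
class VAEModel:
    config: VAEConfig
    vocab: Vocabulary
    params: dict[str, Tensor]

    @classmethod
    def init(cls, config: VAEConfig, vocab: Vocabulary, rng: np.random.Generator) -> "VAEModel":
        p: dict[str, Tensor] = {}
        c_in = len(vocab)
        length = config.max_len
        for i, (k, c_out) in enumerate(zip(config.conv_kernels, config.conv_channels)):
            p[f"conv{i}_w"] = nn.xavier_uniform((k, c_in, c_out), rng, fan_in=k * c_in)
            p[f"conv{i}_b"] = nn.parameter(np.zeros(c_out))
            c_in = c_out
            length = length - k + 1
        flat = length * c_in
        p["dense_w"] = nn.xavier_uniform((flat, config.dense_hidden), rng)
        p["dense_b"] = nn.parameter(np.zeros(config.dense_hidden))
        p["mu_w"] = nn.xavier_uniform((config.dense_hidden, config.latent_dim), rng)
        p["mu_b"] = nn.parameter(np.zeros(config.latent_dim))
        p["logvar_w"] = nn.xavier_uniform((config.dense_hidden, config.latent_dim), rng)
        p["logvar_b"] = nn.parameter(np.zeros(config.latent_dim))
        h = config.gru_hidden
        in_dim = config.latent_dim
        for l in range(config.gru_layers):
            p[f"gru{l}_wx"] = nn.xavier_uniform((in_dim, 3 * h), rng)
            p[f"gru{l}_wh"] = nn.xavier_uniform((h, 3 * h), rng)
            p[f"gru{l}_bx"] = nn.parameter(np.zeros(3 * h))
            p[f"gru{l}_bh"] = nn.parameter(np.zeros(3 * h))
            in_dim = h
        p["out_w"] = nn.xavier_uniform((h, len(vocab)), rng)
        p["out_b"] = nn.parameter(np.zeros(len(vocab)))
        return cls(config=config, vocab=vocab, params=p)

    @property
    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    # -- forward pieces ----------------------------------------------------

    def encode(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """(batch, max_len, |vocab|) one-hot -> posterior (mu, logvar)."""
        h = x
        for i in range(len(self.config.conv_kernels)):
            h = nn.conv1d(h, self.params[f"conv{i}_w"], self.params[f"conv{i}_b"]).selu()
        b = h.shape[0]
        h = h.reshape(b, -1)
        h = (h @ self.params["dense_w"] + self.params["dense_b"]).selu()
        mu = h @ self.params["mu_w"] + self.params["mu_b"]
        logvar = h @ self.params["logvar_w"] + self.params["logvar_b"]
        return mu, logvar

    def _gru_step(self, layer: int, x: Tensor, h: Tensor) -> Tensor:
        return nn.gru_step(
            x, h,
            self.params[f"gru{layer}_wx"], self.params[f"gru{layer}_wh"],
            self.params[f"gru{layer}_bx"], self.params[f"gru{layer}_bh"],
        )

    def decode_step_probs(self, z: Tensor, hiddens: list[Tensor]) -> tuple[Tensor, list[Tensor]]:
        x = z
        new_hiddens = []
        for l in range(self.config.gru_layers):
            hn = self._gru_step(l, x, hiddens[l])
            new_hiddens.append(hn)
            x = hn
        probs = (x @ self.params["out_w"] + self.params["out_b"]).softmax(axis=-1)
        return probs, new_hiddens

    def reconstruction_bce(self, z: Tensor, targets: np.ndarray) -> Tensor:
        """Mean BCE of the softmax outputs against the one-hot targets."""
        b = z.shape[0]
        hiddens = [Tensor(np.zeros((b, self.config.gru_hidden)))
                   for _ in range(self.config.gru_layers)]
        total: Tensor | None = None
        for t in range(self.config.max_len):
            probs, hiddens = self.decode_step_probs(z, hiddens)
            step = nn.bce(probs, targets[:, t, :])
            total = step if total is None else total + step
        return total * (1.0 / self.config.max_len)


def kl_divergence(mu: Tensor, logvar: Tensor) -> Tensor:
    """KL(N(mu, diag exp(logvar)) || N(0, I)), mean over the batch.

    Zero exactly when the posterior equals the prior (mu=0, logvar=0).
    """
    term = 1.0 + logvar - mu * mu - logvar.exp()
    return (-0.5) * term.sum(axis=1).mean()


def vae_loss(model: VAEModel, batch: np.ndarray, rng: np.random.Generator,
             training: bool = True) -> Tensor:
    """0.5 * BCE + 0.5 * KL on a one-hot batch (batch, max_len, |vocab|)."""
    x = Tensor(batch)
    mu, logvar = model.encode(x)
    if training:
        eps = Tensor(rng.standard_normal(mu.shape))
        z = mu + (0.5 * logvar).exp() * eps
    else:
        z = mu
    rec = model.reconstruction_bce(z, batch)
    kl = kl_divergence(mu, logvar)
    cfg = model.config
    return cfg.bce_weight * rec + cfg.kl_weight * kl


# ---------------------------------------------------------------------------
# training


def train_vae(corpus: Sequence[str], config: VAEConfig) -> tuple[VAEModel, dict]:
    """Train on a corpus of accepted SMILES; returns the model and a loss log.

    Mirrors the GAE trainer: one weight set trained through a k-fold loop,
    Adam with plateau-halving learning rate, halting at the floor rate or
    zero loss; NaN loss aborts with diagnostics.
    """
    if len(corpus) < 2:
        raise ValueError("training requires at least 2 SMILES")
    too_long = [s for s in corpus if len(s) > config.max_len]
    if too_long:
        raise ValueError(
            f"{len(too_long)} SMILES exceed max_len={config.max_len}; filter first"
        )
    rng = np.random.default_rng(config.seed)
    vocab = Vocabulary.from_corpus(corpus)
    model = VAEModel.init(config, vocab, rng)
    onehots = np.stack([smiles_onehot(s, vocab, config.max_len) for s in corpus])

    opt = Adam(model.parameters, lr=config.lr_init)
    sched = PlateauHalving(opt, floor=config.lr_floor)
    idx = rng.permutation(len(corpus))
    folds = np.array_split(idx, config.folds) if config.folds > 1 else [np.array([], dtype=int)]
    log: dict = {"epoch_losses": [], "val_losses": [], "lr": [], "halted": False}

    for fold_i, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(idx, val_idx)
        for _ in range(config.epochs):
            order = rng.permutation(train_idx)
            batch_losses = []
            for start in range(0, len(order), config.batch_size):
                batch = onehots[order[start:start + config.batch_size]]
                opt.zero_grad()
                loss = vae_loss(model, batch, rng, training=True)
                if not np.isfinite(loss.data):
                    raise TrainingDivergedError(
                        f"non-finite loss in fold {fold_i} (lr={opt.lr:g})"
                    )
                loss.backward()
                opt.step()
                batch_losses.append(float(loss.data))
            epoch_loss = float(np.mean(batch_losses))
            log["epoch_losses"].append(epoch_loss)
            log["lr"].append(opt.lr)
            sched.step(epoch_loss)
            if sched.halted or epoch_loss == 0.0:
                log["halted"] = True
                break
        if len(val_idx):
            val = vae_loss(model, onehots[val_idx], rng, training=False)
            log["val_losses"].append(float(val.data))
        if log["halted"]:
            break
    return model, log


# ---------------------------------------------------------------------------
# fingerprints


def vae_fingerprint(smiles: str, model: VAEModel) -> np.ndarray:
    """Posterior mean vector (length latent_dim); deterministic, no sampling."""
    x = smiles_onehot(smiles, model.vocab, model.config.max_len)[None]
    mu, _ = model.encode(Tensor(x))
    return mu.data[0].copy()


def vae_fingerprint_matrix(
    items: Sequence[tuple[str, str]], model: VAEModel
) -> FingerprintMatrix:
    ids = [i for i, _ in items]
    onehots = np.stack(
        [smiles_onehot(s, model.vocab, model.config.max_len) for _, s in items]
    )
    mu, _ = model.encode(Tensor(onehots))
    return FingerprintMatrix(
        values=mu.data.copy(), data_format="continuous", fp_type="data",
        fp_subtype="sequence", n_bits=model.config.latent_dim, compound_ids=ids,
        name=f"vae{model.config.latent_dim}",
    )
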