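"""Graph autoencoder fingerprints.

The encoder stacks seven graph-convolution layers, each a sum-aggregation
over the self-loop-normalized adjacency followed by ReLU:

    H_{l+1} = ReLU(A_norm H_l W_l),   H_0 = the 54-column atom feature matrix

ending in a per-molecule embedding matrix Z of shape |V| x 16.  The decoder
reconstructs the normalized adjacency as ``sigmoid(dropout(Z Z^T))`` and the
loss is elementwise binary cross-entropy with the (soft) A_norm entries as
targets.  Fingerprints are built from Z alone:

* 16 bits — the singular values of Z, descending, zero-padded to 16
  (the diagonal of the SVD's Sigma, in the spirit of the Ky Fan k-norm);
* 64 bits — column-wise mean-, min- and max-pooled Z concatenated with the
  16-bit singular-value block.

Because graph-convolution is permutation-equivariant and singular values are
invariant to row permutations, both fingerprints are invariant to atom
relabeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn
from .nn import Adam, PlateauHalving, Tensor, TrainingDivergedError
from .rulefp import ConfigError, FingerprintMatrix
from .standardize import MolecularGraph


@dataclass
class GAEConfig:
    """Hyperparameters of the graph autoencoder.

    The embedding width is fixed at 16 by the 64-bit fingerprint arithmetic
    (three pooled blocks of 16 plus 16 singular values).  Hidden widths
    interpolate between the 54 input features and the embedding.
    """

    hidden_dims: tuple[int, ...] = (48, 40, 36, 32, 24, 20)
    embedding_dim: int = 16
    dropout: float = 0.1
    lr_init: float = 1e-3
    lr_floor: float = 1e-6
    epochs: int = 40
    folds: int = 5
    batch_size: int = 8
    seed: int = 0
    binary_targets: bool = False  # reconstruct A + I instead of soft A_norm

    def __post_init__(self) -> None:
        if self.embedding_dim < 16:
            raise ConfigError("embedding_dim must be >= 16 (fingerprint construction)")
        if not self.lr_floor < self.lr_init:
            raise ConfigError("lr_floor must be below lr_init")

    @property
    def n_layers(self) -> int:
        return len(self.hidden_dims) + 1

    @property
    def layer_dims(self) -> tuple[int, ...]:
        return (54, *self.hidden_dims, self.embedding_dim)


@dataclass
class GAEModel:
    config: GAEConfig
    weights: list[Tensor]

    @classmethod
    def init(cls, config: GAEConfig, rng: np.random.Generator) -> "GAEModel":
        dims = config.layer_dims
        weights = [nn.xavier_uniform((a, b), rng) for a, b in zip(dims[:-1], dims[1:])]
        return cls(config=config, weights=weights)


def gae_encode(graph: MolecularGraph, model: GAEModel) -> np.ndarray:
    """Per-node embedding matrix Z (|V| x 16); deterministic, dropout off."""
    h = graph.node_features
    if h.shape[1] != model.config.layer_dims[0]:
        raise ConfigError(
            f"node features have {h.shape[1]} columns, expected {model.config.layer_dims[0]}"
        )
    for w in model.weights:
        h = np.maximum(graph.adjacency_norm @ h @ w.data, 0.0)
    return h


def gae_decode(
    z: np.ndarray,
    training: bool = False,
    dropout: float = 0.1,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """``sigmoid(dropout(Z Z^T))``; symmetric with entries in (0,1) at inference."""
    logits = z @ z.T
    if training and dropout > 0.0:
        if rng is None:
            raise ValueError("training-mode decode needs an rng for dropout")
        logits = logits * ((rng.random(logits.shape) >= dropout) / (1.0 - dropout))
    return 1.0 / (1.0 + np.exp(-logits))


def gae_loss(reconstruction: np.ndarray, target: np.ndarray, eps: float = 1e-7) -> float:
    """Mean elementwise binary cross-entropy against (soft) A_norm targets.

    Non-negative; at a perfect reconstruction it equals the entropy of the
    targets (zero only when the targets are binary).
    """
    r = np.asarray(reconstruction, dtype=float)
    t = np.asarray(target, dtype=float)
    if r.shape != t.shape:
        raise ValueError(f"shape mismatch: {r.shape} vs {t.shape}")
    rc = np.clip(r, eps, 1.0 - eps)
    return float(np.mean(-(t * np.log(rc) + (1.0 - t) * np.log(1.0 - rc))))


# ---------------------------------------------------------------------------
# training


def _pad_batch(graphs: Sequence[MolecularGraph], binary_targets: bool):
    """Zero-pad a batch to its max node count; empty nodes stay all-zero."""
    n = max(g.node_count for g in graphs)
    b = len(graphs)
    anorm = np.zeros((b, n, n))
    feats = np.zeros((b, n, 54))
    target = np.zeros((b, n, n))
    mask = np.zeros((b, n, n))
    for i, g in enumerate(graphs):
        v = g.node_count
        anorm[i, :v, :v] = g.adjacency_norm
        target[i, :v, :v] = (
            np.minimum(g.adjacency + np.eye(v), 1.0) if binary_targets else g.adjacency_norm
        )
        feats[i, :v, :] = g.node_features
        mask[i, :v, :v] = 1.0
    return anorm, feats, target, mask


def _forward_batch(
    graphs: Sequence[MolecularGraph],
    model: GAEModel,
    rng: np.random.Generator,
    training: bool,
) -> Tensor:
    anorm_np, feats, target, mask = _pad_batch(graphs, model.config.binary_targets)
    anorm = Tensor(anorm_np)
    h = Tensor(feats)
    for w in model.weights:
        h = ((anorm @ h) @ w).relu()
    logits = h @ h.transpose_last2()
    logits = logits.dropout(model.config.dropout, rng, training=training)
    recon = logits.sigmoid()
    return nn.bce(recon, target, mask=mask)


def train_gae(
    graphs: Sequence[MolecularGraph], config: GAEConfig
) -> tuple[GAEModel, dict]:
    """Train the autoencoder with a k-fold loop; returns model and loss log.

    One set of weights is trained throughout; each fold contributes
    ``config.epochs`` epochs on its training portion and a validation loss on
    its held-out portion.  Training halts early when the plateau-halving
    learning rate reaches its floor or the loss reaches zero; NaN loss aborts.
    """
    if len(graphs) < 2:
        raise ValueError("training requires at least 2 graphs")
    rng = np.random.default_rng(config.seed)
    model = GAEModel.init(config, rng)
    opt = Adam(model.weights, lr=config.lr_init)
    sched = PlateauHalving(opt, floor=config.lr_floor)

    idx = rng.permutation(len(graphs))
    folds = np.array_split(idx, config.folds) if config.folds > 1 else [np.array([], dtype=int)]
    log: dict = {"epoch_losses": [], "val_losses": [], "lr": [], "halted": False}

    for fold_i, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(idx, val_idx)
        for _ in range(config.epochs):
            order = rng.permutation(train_idx)
            batch_losses = []
            for start in range(0, len(order), config.batch_size):
                batch = [graphs[j] for j in order[start:start + config.batch_size]]
                opt.zero_grad()
                loss = _forward_batch(batch, model, rng, training=True)
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
            val = _forward_batch([graphs[j] for j in val_idx], model, rng, training=False)
            log["val_losses"].append(float(val.data))
        if log["halted"]:
            break
    return model, log


# ---------------------------------------------------------------------------
# fingerprints


def gae_fingerprint_16(z: np.ndarray, n_bits: int = 16) -> np.ndarray:
    """Singular values of Z, descending, zero-padded/truncated to 16."""
    z = np.asarray(z, dtype=float)
    s = np.linalg.svd(z, compute_uv=False)
    out = np.zeros(n_bits)
    k = min(n_bits, s.size)
    out[:k] = s[:k]
    return out


def gae_fingerprint_64(z: np.ndarray) -> np.ndarray:
    """concat(column-mean, column-min, column-max, singular-value block)."""
    z = np.asarray(z, dtype=float)
    if z.ndim != 2 or z.shape[1] != 16:
        raise ConfigError(f"expected a |V| x 16 embedding, got {z.shape}")
    return np.concatenate(
        [z.mean(axis=0), z.min(axis=0), z.max(axis=0), gae_fingerprint_16(z)]
    )


def gae_fingerprint_matrix(
    items: Sequence[tuple[str, MolecularGraph]], model: GAEModel, n_bits: int = 64
) -> FingerprintMatrix:
    """Fingerprint ``(id, graph)`` pairs with a trained model."""
    if n_bits not in (16, 64):
        raise ConfigError(f"GAE fingerprints are 16 or 64 bits, got {n_bits}")
    fn = gae_fingerprint_16 if n_bits == 16 else gae_fingerprint_64
    ids = [i for i, _ in items]
    values = np.stack([fn(gae_encode(g, model)) for _, g in items])
    return FingerprintMatrix(
        values=values, data_format="continuous", fp_type="data", fp_subtype="graph",
        n_bits=n_bits, compound_ids=ids, name=f"gae{n_bits}",
    )
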