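"""Multimodal feature fusion via an autoencoder latent space.

Expression and pathomics tables are inner-joined on sample ID into one
sample-by-feature matrix (columns prefixed ``expr_`` / ``path_``), split
7:3 into training and validation partitions, z-scored with training-set
statistics only, and compressed by a fully connected autoencoder whose
encoder stack is 128 -> 64 -> 32 units (ReLU hidden activations, linear
latent, mirrored decoder). Training uses mean-squared reconstruction error,
dropout 0.1 on hidden activations, mini-batch SGD with batch size 64,
learning rate 0.001 and 150 epochs; all randomness (init, shuffling,
dropout) derives from the config seed, so training is bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AEConfig", "ColumnStats", "LatentModel",
           "assemble", "split", "zscore_fit", "zscore_apply",
           "train_autoencoder", "encode"]


@dataclass
class AEConfig:
    hidden_sizes: tuple = (128, 64, 32)
    dropout: float = 0.1
    batch_size: int = 64
    learning_rate: float = 0.001
    epochs: int = 150
    seed: int = 0

    def __post_init__(self):
        if min(self.hidden_sizes) <= 0 or self.batch_size <= 0 \
                or self.learning_rate <= 0 or self.epochs <= 0:
            raise ValueError("AEConfig values must be positive")

    @property
    def latent_dim(self):
        return self.hidden_sizes[-1]


@dataclass
class ColumnStats:
    mean: pd.Series
    sd: pd.Series


def assemble(expr, path, expr_prefix="expr_", path_prefix="path_"):
    """Inner-join expression and pathomics tables on sample ID.

    Both inputs are samples x features DataFrames indexed by sample ID.
    Columns are prefixed per modality (unless already prefixed), so name
    collisions across modalities are impossible. Samples present in only
    one modality are dropped with a warning.
    """
    for t, name in ((expr, "expr"), (path, "path")):
        if t.index.duplicated().any():
            raise ValueError(f"duplicate sample IDs in {name} table")
    e = expr.rename(columns={c: c if str(c).startswith(expr_prefix)
                             else f"{expr_prefix}{c}" for c in expr.columns})
    p = path.rename(columns={c: c if str(c).startswith(path_prefix)
                             else f"{path_prefix}{c}" for c in path.columns})
    shared = e.index.intersection(p.index)
    if len(shared) == 0:
        raise ValueError("no shared samples between modalities")
    dropped = len(e.index.union(p.index)) - len(shared)
    if dropped:
        warnings.warn(f"{dropped} samples present in one modality only; dropped")
    out = e.loc[shared].join(p.loc[shared])
    if out.isna().any().any():
        raise ValueError("assembled table contains NA values")
    return out


def split(table, ratio=0.7, seed=0):
    """Deterministic train/validation sample split (|train| = round(r*n))."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    n = len(table)
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(round(ratio * n))
    idx = table.index.to_numpy()
    return idx[np.sort(order[:n_train])], idx[np.sort(order[n_train:])]


def zscore_fit(train_table):
    sd = train_table.std(axis=0, ddof=0).replace(0.0, 1.0)
    return ColumnStats(mean=train_table.mean(axis=0), sd=sd)


def zscore_apply(table, stats):
    return (table - stats.mean) / stats.sd


def _glorot(rng, fan_in, fan_out):
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


@dataclass
class LatentModel:
    config: AEConfig
    columns: list
    stats: ColumnStats
    weights: list = field(repr=False, default=None)   # per layer (W, b)
    loss_trace: np.ndarray = None

    @property
    def n_encoder_layers(self):
        return len(self.config.hidden_sizes)


def _forward(weights, x, n_enc, dropout=0.0, rng=None):
    """Returns per-layer activations; dropout on hidden (ReLU) layers only."""
    acts = [x]
    masks = [None]
    h = x
    n_layers = len(weights)
    for li, (W, b) in enumerate(weights):
        h = h @ W + b
        is_latent = li == n_enc - 1
        is_output = li == n_layers - 1
        if not (is_latent or is_output):
            h = np.maximum(h, 0.0)
            if dropout > 0.0 and rng is not None:
                m = (rng.random(h.shape) >= dropout) / (1.0 - dropout)
                h = h * m
                masks.append(m)
            else:
                masks.append(None)
        else:
            masks.append(None)
        acts.append(h)
    return acts, masks


def train_autoencoder(train_table, cfg=None):
    """Fit the autoencoder on a z-scored (or raw) training table.

    Returns a :class:`LatentModel` holding the weights, per-epoch mean
    reconstruction MSE and the column statistics used for z-scoring (fit
    here if the table is not already standardized — callers normally pass
    raw feature values and let this function own the scaling).
    """
    cfg = cfg or AEConfig()
    stats = zscore_fit(train_table)
    x_all = zscore_apply(train_table, stats).to_numpy(float)
    n, d = x_all.shape
    if d < cfg.latent_dim:
        raise ValueError("feature dimension below latent dimension")
    sizes = [d, *cfg.hidden_sizes]                 # encoder
    sizes += list(cfg.hidden_sizes[-2::-1]) + [d]  # mirrored decoder
    rng = np.random.default_rng(cfg.seed)
    weights = [(_glorot(rng, a, b), np.zeros(b)) for a, b in zip(sizes[:-1], sizes[1:])]
    n_enc = len(cfg.hidden_sizes)
    bs = min(cfg.batch_size, n)
    trace = np.empty(cfg.epochs)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, bs):
            xb = x_all[order[s:s + bs]]
            acts, masks = _forward(weights, xb, n_enc, cfg.dropout, rng)
            recon = acts[-1]
            err = recon - xb
            loss = float(np.mean(err ** 2))
            losses.append(loss)
            # backprop MSE through the stack
            grad = 2.0 * err / err.size
            for li in range(len(weights) - 1, -1, -1):
                W, b = weights[li]
                a_in = acts[li]
                is_latent = li == n_enc - 1
                is_output = li == len(weights) - 1
                if not (is_latent or is_output):
                    post = acts[li + 1]
                    grad = grad * (post > 0) if masks[li + 1] is None else \
                        grad * masks[li + 1] * ((a_in @ W + b) > 0)
                gW = a_in.T @ grad
                gb = grad.sum(axis=0)
                grad = grad @ W.T
                weights[li] = (W - cfg.learning_rate * gW,
                               b - cfg.learning_rate * gb)
        trace[epoch] = float(np.mean(losses))
        if not np.isfinite(trace[epoch]):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
    return LatentModel(config=cfg, columns=list(train_table.columns),
                       stats=stats, weights=weights, loss_trace=trace)


def encode(model, table):
    """Deterministic forward pass to the latent layer (dropout disabled)."""
    missing = [c for c in model.columns if c not in table.columns]
    extra = [c for c in table.columns if c not in model.columns]
    if missing or extra:
        raise ValueError(f"column mismatch: missing={missing}, extra={extra}")
    x = zscore_apply(table[model.columns], model.stats).to_numpy(float)
    n_enc = model.n_encoder_layers
    h = x
    for li in range(n_enc):
        W, b = model.weights[li]
        h = h @ W + b
        if li < n_enc - 1:
            h = np.maximum(h, 0.0)
    return pd.DataFrame(h, index=table.index,
                        columns=[f"latent_{j}" for j in range(h.shape[1])])


def reconstruct(model, table):
    """Full forward pass (encode + decode), dropout disabled."""
    x = zscore_apply(table[model.columns], model.stats).to_numpy(float)
    acts, _ = _forward(model.weights, x, model.n_encoder_layers)
    return acts[-1]


def reconstruction_mse(model, table):
    x = zscore_apply(table[model.columns], model.stats).to_numpy(float)
    return float(np.mean((reconstruct(model, table) - x) ** 2))
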