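"""Distance-preserving embedding learned jointly with a denoising autoencoder.

Two networks share the (log-normalized) expression input: an autoencoder
``f_a`` that reconstructs/imputes expression, and an encoder ``f_m`` whose
low-dimensional output is trained so that squared Euclidean distances
between embedded cells track squared distances between the *imputed*
expression vectors. Training runs in two stages over mini-batches of cell
pairs: a reconstruction-only pre-training stage, then joint tuning of

    L = L_rec + alpha * L_dist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import MLP, Adam
from .io import ExpressionMatrix

__all__ = [
    "EmbeddingConfig",
    "EmbeddingModel",
    "sample_pair_batch",
    "reconstruction_loss",
    "mds_loss",
    "joint_loss",
    "train_embedding",
    "embed",
    "impute",
]


@dataclass
class EmbeddingConfig:
    """Hyperparameters for the paired autoencoder/encoder model."""

    latent_dim: int = 256
    ae_hidden_widths: tuple[int, ...] = (1024, 512)
    mds_hidden_widths: tuple[int, ...] = (1024, 512)
    alpha: float = 1.0
    dropout_rate: float = 0.3
    pretrain_steps: int = 1000
    max_joint_steps: int = 40000
    batch_pairs: int = 256
    early_stop: bool = True
    early_stop_tol: float = 1e-4
    early_stop_patience: int = 100
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.batch_pairs < 1:
            raise ValueError("batch_pairs must be at least 1")


@dataclass
class EmbeddingModel:
    """Trained autoencoder + distance-preserving encoder."""

    ae: MLP
    mds: MLP
    config: EmbeddingConfig
    n_genes: int
    training_log: dict = field(default_factory=dict)


def sample_pair_batch(
    n_cells: int, batch_pairs: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample ``batch_pairs`` uniformly random index pairs (i != j).

    Returns an integer array of shape (batch_pairs, 2).
    """
    if n_cells < 2:
        raise ValueError("need at least 2 cells to form pairs")
    if batch_pairs < 1:
        raise ValueError("batch_pairs must be at least 1")
    i = rng.integers(0, n_cells, size=batch_pairs)
    # second index drawn from the other n-1 cells, shifted past i
    j = rng.integers(0, n_cells - 1, size=batch_pairs)
    j = np.where(j >= i, j + 1, j)
    return np.stack([i, j], axis=1)


def _as_pair_array(pairs, name: str) -> np.ndarray:
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 3 or arr.shape[1] != 2:
        raise ValueError(f"{name} must have shape (n_pairs, 2, dim)")
    return arr


def reconstruction_loss(x_pairs, xhat_pairs) -> float:
    """Mean squared reconstruction error over a pair batch.

    ``(1 / (2 P)) * sum over pairs of (||x_i - xhat_i||^2 + ||x_j - xhat_j||^2)``.
    """
    x = _as_pair_array(x_pairs, "x_pairs")
    xh = _as_pair_array(xhat_pairs, "xhat_pairs")
    if x.shape != xh.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {xh.shape}")
    p = x.shape[0]
    return float(np.sum((x - xh) ** 2) / (2 * p))


def mds_loss(z_pairs, xhat_pairs) -> float:
    """Mean |squared embedding distance - squared imputed distance| over pairs."""
    z = _as_pair_array(z_pairs, "z_pairs")
    xh = _as_pair_array(xhat_pairs, "xhat_pairs")
    if z.shape[0] != xh.shape[0]:
        raise ValueError(
            f"pair count mismatch: {z.shape[0]} embeddings vs {xh.shape[0]} imputed"
        )
    dz2 = np.sum((z[:, 0] - z[:, 1]) ** 2, axis=1)
    dx2 = np.sum((xh[:, 0] - xh[:, 1]) ** 2, axis=1)
    return float(np.mean(np.abs(dz2 - dx2)))


def joint_loss(rec: float, mds: float, alpha: float) -> float:
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return float(rec) + float(alpha) * float(mds)


def _check_lognorm(m: ExpressionMatrix) -> np.ndarray:
    if m.layer != "lognorm":
        raise ValueError("expected a lognorm-layer matrix; preprocess first")
    return m.values


def train_embedding(m: ExpressionMatrix, cfg: EmbeddingConfig) -> EmbeddingModel:
    """Two-stage training: reconstruction pre-training, then joint tuning."""
    x_all = _check_lognorm(m)
    n, g = x_all.shape
    if n < 2:
        raise ValueError("need at least 2 cells to train")
    if cfg.latent_dim >= g:
        raise ValueError(
            f"latent_dim ({cfg.latent_dim}) must be smaller than the gene count ({g})"
        )

    rng = np.random.default_rng(cfg.seed)
    ae_widths = [g, *cfg.ae_hidden_widths, cfg.latent_dim,
                 *reversed(cfg.ae_hidden_widths), g]
    mds_widths = [g, *cfg.mds_hidden_widths, cfg.latent_dim]
    ae = MLP(ae_widths, rng, dropout_rate=cfg.dropout_rate)
    mds = MLP(mds_widths, rng, dropout_rate=0.0)
    opt_ae = Adam(ae.params, lr=cfg.learning_rate)
    opt_joint = Adam(ae.params + mds.params, lr=cfg.learning_rate)

    log: dict = {"pretrain": [], "joint": [], "joint_rec": [], "joint_mds": []}

    def batch_rows():
        pairs = sample_pair_batch(n, cfg.batch_pairs, rng)
        x = np.concatenate([x_all[pairs[:, 0]], x_all[pairs[:, 1]]], axis=0)
        return x

    p = cfg.batch_pairs
    for step in range(cfg.pretrain_steps):
        x = batch_rows()
        xhat, cache = ae.forward(x, train=True, rng=rng)
        loss = float(np.sum((x - xhat) ** 2) / (2 * p))
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite loss at pre-training step {step}")
        log["pretrain"].append(loss)
        grads, _ = ae.backward((xhat - x) / p, cache)
        opt_ae.step(grads)

    best = np.inf
    stall = 0
    for step in range(cfg.max_joint_steps):
        x = batch_rows()
        xhat, cache_ae = ae.forward(x, train=True, rng=rng)
        z, cache_m = mds.forward(x, train=False)
        xi, xj = xhat[:p], xhat[p:]
        zi, zj = z[:p], z[p:]
        diff_x = xi - xj
        diff_z = zi - zj
        dx2 = np.sum(diff_x**2, axis=1)
        dz2 = np.sum(diff_z**2, axis=1)
        rec = float(np.sum((x - xhat) ** 2) / (2 * p))
        dist = float(np.mean(np.abs(dz2 - dx2)))
        loss = rec + cfg.alpha * dist
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite loss at joint step {step}")
        log["joint"].append(loss)
        log["joint_rec"].append(rec)
        log["joint_mds"].append(dist)

        s = np.sign(dz2 - dx2)[:, None]
        gz = np.concatenate(
            [(2 * cfg.alpha / p) * s * diff_z, -(2 * cfg.alpha / p) * s * diff_z]
        )
        gx_mds = np.concatenate(
            [-(2 * cfg.alpha / p) * s * diff_x, (2 * cfg.alpha / p) * s * diff_x]
        )
        gxhat = (xhat - x) / p + gx_mds
        g_ae, _ = ae.backward(gxhat, cache_ae)
        g_m, _ = mds.backward(gz, cache_m)
        opt_joint.step(g_ae + g_m)

        if cfg.early_stop:
            if loss < best * (1.0 - cfg.early_stop_tol):
                best = loss
                stall = 0
            else:
                best = min(best, loss)
                stall += 1
                if stall >= cfg.early_stop_patience:
                    break

    return EmbeddingModel(ae=ae, mds=mds, config=cfg, n_genes=g, training_log=log)


def _check_width(model: EmbeddingModel, m: ExpressionMatrix) -> np.ndarray:
    x = _check_lognorm(m)
    if x.shape[1] != model.n_genes:
        raise ValueError(
            f"matrix has {x.shape[1]} genes but the model expects {model.n_genes}"
        )
    return x


def embed(model: EmbeddingModel, m: ExpressionMatrix) -> np.ndarray:
    """Inference-mode embedding: row i = f_m(x_i)."""
    x = _check_width(model, m)
    z, _ = model.mds.forward(x, train=False)
    return z


def impute(model: EmbeddingModel, m: ExpressionMatrix) -> np.ndarray:
    """Inference-mode imputed expression: row i = f_a(x_i)."""
    x = _check_width(model, m)
    xhat, _ = model.ae.forward(x, train=False)
    return xhat
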