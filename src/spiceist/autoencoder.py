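"""Graph-convolutional autoencoder with a dual reconstruction objective.

The encoder is a GCN block of width 128 (GCN -> batch norm -> ReLU ->
dropout(p=0.2)) followed by a second GCN block to the 64-D latent built as
GCN -> batch norm -> dropout, without a rectification; graph convolution
propagates node features over the symmetric-normalized adjacency with
self-loops, D^-1/2 (A+I) D^-1/2.  The latent block keeps its batch norm —
which balances the variance of the latent dimensions so fine subcellular
structure is not drowned by the dominant cell-level directions — but stays
unrectified so the pooled cell latent can match the signed PCA target
exactly in the large-alpha limit.  The decoder is a node-wise MLP,
FC -> BN -> ReLU -> dropout -> FC, that reconstructs the M-dimensional
subcellular features.  Training minimizes

    L = L_recon + alpha * L_embed

where L_recon averages the per-cell mean squared node-feature
reconstruction error and L_embed is the mean squared error, averaged over
the 64 latent dimensions and over cells, between each cell's mean-pooled
latent and its cell-level PCA vector z_c.  Both terms are per-element MSE
losses, so their scales are comparable and alpha has its intended meaning:
a small alpha emphasizes subcellular structure; a large alpha pins the
latent to the conventional expression embedding.

The network, its gradients and the Adam optimizer are implemented directly
on numpy/scipy arrays, so training is deterministic given the seed and has
no framework dependency.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .graphs import BatchedGraphs, CellGraph, batch_graphs

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass
class ModelConfig:
    """Architecture hyperparameters."""

    n_genes: int
    hidden_dim: int = 128
    latent_dim: int = 64
    decoder_hidden_dim: int = 128
    dropout: float = 0.2

    def __post_init__(self) -> None:
        if min(self.n_genes, self.hidden_dim, self.latent_dim, self.decoder_hidden_dim) < 1:
            raise ValueError("all layer dimensions must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class TrainConfig:
    """Optimization protocol.

    Defaults follow the training recipe: Adam at lr 1e-3, 50 epochs of 32
    random mini-batches each, an 80:20 train/validation split, and early
    stopping once the validation loss fails to improve on the best by more
    than 1e-4 for 3 consecutive epochs.
    """

    alpha: float = 0.25
    lr: float = 1e-3
    epochs: int = 50
    batches_per_epoch: int = 32
    batch_size: int = 32
    val_fraction: float = 0.2
    early_stop_min_delta: float = 1e-4
    early_stop_patience: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")


@dataclass
class LossBreakdown:
    """The two loss components and their weighted sum."""

    reconstruction: float
    embedding: float
    alpha: float

    @property
    def total(self) -> float:
        return self.reconstruction + self.alpha * self.embedding


def compute_loss(
    recon: np.ndarray,
    input_feat: np.ndarray,
    pooled: np.ndarray,
    targets: np.ndarray,
    alpha: float,
    cell_index: np.ndarray,
    n_target_dims: int | None = None,
) -> LossBreakdown:
    """Evaluate the dual objective exactly.

    ``recon``/``input_feat`` are node x gene matrices, ``pooled``/``targets``
    cell x latent matrices, and ``cell_index`` maps each node to its cell.
    L_recon averages the squared error first over a cell's nodes x genes,
    then over cells; L_embed averages the squared pooled-latent error over
    the target dimensions and over cells (per-element MSE, matching the
    reconstruction term's normalization).  When the cell target has rank
    K < latent_dim (possible only for small gene panels), ``n_target_dims``
    restricts L_embed to the K constrained dimensions; the remaining latent
    dimensions carry no target and are shaped by reconstruction alone.
    """
    for name, arr in (("recon", recon), ("input", input_feat), ("pooled", pooled), ("targets", targets)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite values in {name}")
    C = pooled.shape[0]
    M = recon.shape[1]
    K = pooled.shape[1] if n_target_dims is None else n_target_dims
    sq = ((recon - input_feat) ** 2).sum(axis=1)
    per_cell = np.bincount(cell_index, weights=sq, minlength=C)
    sizes = np.bincount(cell_index, minlength=C)
    l1 = float(np.mean(per_cell / (sizes * M)))
    l2 = float(np.mean((pooled[:, :K] - targets[:, :K]) ** 2))
    return LossBreakdown(reconstruction=l1, embedding=l2, alpha=alpha)


class EarlyStopper:
    """Best-checkpoint early stopping on the validation loss.

    An epoch "improves" when its loss beats the current best by strictly
    more than ``min_delta``; only improving epochs update the best
    checkpoint.  Training stops after ``patience`` consecutive
    non-improving epochs.
    """

    def __init__(self, min_delta: float = 1e-4, patience: int = 3):
        self.min_delta = min_delta
        self.patience = patience
        self.best = np.inf
        self.best_epoch: int | None = None
        self.bad_epochs = 0

    def update(self, loss: float, epoch: int) -> tuple[bool, bool]:
        """Record an epoch's loss; returns (improved, stop)."""
        if self.best - loss > self.min_delta:
            self.best = loss
            self.best_epoch = epoch
            self.bad_epochs = 0
            return True, False
        self.bad_epochs += 1
        return False, self.bad_epochs >= self.patience


def early_stopping_trace(
    val_losses: Sequence[float], min_delta: float = 1e-4, patience: int = 3
) -> tuple[int, int]:
    """Apply the early-stopping rule to a loss sequence.

    Returns (number of epochs actually run, best-checkpoint epoch), both
    1-based, for a hypothetical training whose validation losses are
    ``val_losses``.
    """
    stopper = EarlyStopper(min_delta=min_delta, patience=patience)
    for epoch, loss in enumerate(val_losses, start=1):
        _, stop = stopper.update(float(loss), epoch)
        if stop:
            return epoch, stopper.best_epoch
    return len(val_losses), stopper.best_epoch


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _bn_forward(x, gamma, beta, running_mean, running_var, training):
    if training:
        mu = x.mean(axis=0)
        var = x.var(axis=0)
        running_mean *= 1.0 - _BN_MOMENTUM
        running_mean += _BN_MOMENTUM * mu
        running_var *= 1.0 - _BN_MOMENTUM
        running_var += _BN_MOMENTUM * var
    else:
        mu, var = running_mean, running_var
    istd = 1.0 / np.sqrt(var + _BN_EPS)
    xhat = (x - mu) * istd
    return gamma * xhat + beta, (xhat, istd, gamma)


def _bn_backward(dy, cache):
    xhat, istd, gamma = cache
    n = dy.shape[0]
    dgamma = (dy * xhat).sum(axis=0)
    dbeta = dy.sum(axis=0)
    dxhat = dy * gamma
    dx = (istd / n) * (n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
    return dx, dgamma, dbeta


def _dropout_mask(rng, shape, p):
    if p <= 0.0 or rng is None:
        return None
    return (rng.random(shape) >= p) / (1.0 - p)


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class GraphAutoencoder(TransformerMixin, BaseEstimator):
    """Fit the dual-objective graph autoencoder; transform graphs to latents.

    Parameters mirror :class:`ModelConfig` and :class:`TrainConfig`; see the
    module docstring for the architecture.  ``fit`` expects a list of
    :class:`~spiceist.graphs.CellGraph`; ``transform`` returns the cell x 64
    mean-pooled latent matrix in evaluation mode (dropout off, batch-norm
    running statistics).

    Fitted attributes
    -----------------
    params_ : dict of weight arrays (best validation checkpoint)
    bn_stats_ : dict of batch-norm running statistics
    history_ : list of per-epoch dicts with train/val loss components
    best_epoch_ : 1-based epoch whose checkpoint was kept
    n_epochs_run_ : epochs actually executed before early stopping
    """

    def __init__(
        self,
        alpha: float = 0.25,
        hidden_dim: int = 128,
        latent_dim: int = 64,
        decoder_hidden_dim: int = 128,
        dropout: float = 0.2,
        lr: float = 1e-3,
        epochs: int = 50,
        batches_per_epoch: int = 32,
        batch_size: int = 32,
        val_fraction: float = 0.2,
        early_stop_min_delta: float = 1e-4,
        early_stop_patience: int = 3,
        random_state: int = 0,
    ):
        self.alpha = alpha
        self.hidden_dim = hidden_dim
        self.latent_dim = latent_dim
        self.decoder_hidden_dim = decoder_hidden_dim
        self.dropout = dropout
        self.lr = lr
        self.epochs = epochs
        self.batches_per_epoch = batches_per_epoch
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.early_stop_min_delta = early_stop_min_delta
        self.early_stop_patience = early_stop_patience
        self.random_state = random_state

    # -- parameter initialisation -------------------------------------------------

    def _init_params(self, n_genes: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        h, k, d = self.hidden_dim, self.latent_dim, self.decoder_hidden_dim
        p = {
            "W_g1": _glorot(rng, n_genes, h), "b_g1": np.zeros(h),
            "gamma1": np.ones(h), "beta1": np.zeros(h),
            "W_g2": _glorot(rng, h, k), "b_g2": np.zeros(k),
            "gamma2": np.ones(k), "beta2": np.zeros(k),
            "W_d1": _glorot(rng, k, d), "b_d1": np.zeros(d),
            "gamma3": np.ones(d), "beta3": np.zeros(d),
            "W_d2": _glorot(rng, d, n_genes), "b_d2": np.zeros(n_genes),
        }
        return p

    def _init_bn_stats(self) -> dict[str, np.ndarray]:
        h, k, d = self.hidden_dim, self.latent_dim, self.decoder_hidden_dim
        return {
            "mean1": np.zeros(h), "var1": np.ones(h),
            "mean2": np.zeros(k), "var2": np.ones(k),
            "mean3": np.zeros(d), "var3": np.ones(d),
        }

    # -- forward / backward -------------------------------------------------------

    def _forward(self, params, bn_stats, batch: BatchedGraphs, training: bool, rng=None):
        """Full forward pass; returns (recon, H2, pooled, cache)."""
        p = self.dropout if training else 0.0
        A, X = batch.adj, batch.X
        if X.shape[1] != params["W_g1"].shape[0]:
            raise ValueError(
                f"node features have {X.shape[1]} genes, model expects {params['W_g1'].shape[0]}"
            )
        cache: dict = {}
        P1 = A @ X
        Z1 = P1 @ params["W_g1"] + params["b_g1"]
        B1, cache["bn1"] = _bn_forward(
            Z1, params["gamma1"], params["beta1"], bn_stats["mean1"], bn_stats["var1"], training
        )
        R1 = np.maximum(B1, 0.0)
        m1 = _dropout_mask(rng, R1.shape, p) if training else None
        H1 = R1 * m1 if m1 is not None else R1

        P2 = A @ H1
        Z2 = P2 @ params["W_g2"] + params["b_g2"]
        B2, cache["bn2"] = _bn_forward(
            Z2, params["gamma2"], params["beta2"], bn_stats["mean2"], bn_stats["var2"], training
        )
        m2 = _dropout_mask(rng, B2.shape, p) if training else None
        H2 = B2 * m2 if m2 is not None else B2  # unrectified latent

        F1 = H2 @ params["W_d1"] + params["b_d1"]
        B3, cache["bn3"] = _bn_forward(
            F1, params["gamma3"], params["beta3"], bn_stats["mean3"], bn_stats["var3"], training
        )
        R3 = np.maximum(B3, 0.0)
        m3 = _dropout_mask(rng, R3.shape, p) if training else None
        D3 = R3 * m3 if m3 is not None else R3
        recon = D3 @ params["W_d2"] + params["b_d2"]

        pooled = batch.pool @ H2
        cache.update(
            P1=P1, B1=B1, m1=m1, H1=H1, P2=P2, m2=m2, H2=H2,
            F1=F1, B3=B3, m3=m3, D3=D3, A=A,
        )
        return recon, H2, pooled, cache

    def _backward(self, params, batch: BatchedGraphs, cache, recon, pooled):
        """Gradients of L = L_recon + alpha * L_embed w.r.t. all parameters."""
        A, X = cache["A"], batch.X
        C = batch.n_cells
        M = X.shape[1]
        w_node = 1.0 / (C * batch.node_sizes[batch.cell_index] * M)

        g: dict[str, np.ndarray] = {}
        K = batch.n_target_dims
        dRecon = 2.0 * w_node[:, None] * (recon - X)
        dPooled = np.zeros_like(pooled)
        dPooled[:, :K] = (2.0 * self.alpha / (C * K)) * (pooled[:, :K] - batch.targets[:, :K])

        # decoder
        g["W_d2"] = cache["D3"].T @ dRecon
        g["b_d2"] = dRecon.sum(axis=0)
        dD3 = dRecon @ params["W_d2"].T
        dR3 = dD3 * cache["m3"] if cache["m3"] is not None else dD3
        dB3 = dR3 * (cache["B3"] > 0)
        dF1, g["gamma3"], g["beta3"] = _bn_backward(dB3, cache["bn3"])
        g["W_d1"] = cache["H2"].T @ dF1
        g["b_d1"] = dF1.sum(axis=0)
        dH2 = dF1 @ params["W_d1"].T
        dH2 = dH2 + batch.pool.T @ dPooled

        # encoder latent block (GCN -> BN -> dropout, unrectified)
        dB2 = dH2 * cache["m2"] if cache["m2"] is not None else dH2
        dZ2, g["gamma2"], g["beta2"] = _bn_backward(dB2, cache["bn2"])
        g["W_g2"] = cache["P2"].T @ dZ2
        g["b_g2"] = dZ2.sum(axis=0)
        dP2 = dZ2 @ params["W_g2"].T
        dH1 = A.T @ dP2

        # encoder block 1
        dR1 = dH1 * cache["m1"] if cache["m1"] is not None else dH1
        dB1 = dR1 * (cache["B1"] > 0)
        dZ1, g["gamma1"], g["beta1"] = _bn_backward(dB1, cache["bn1"])
        g["W_g1"] = cache["P1"].T @ dZ1
        g["b_g1"] = dZ1.sum(axis=0)
        return g

    def loss_and_grads(self, params, bn_stats, batch: BatchedGraphs, training=True, rng=None):
        """One forward/backward pass; returns (LossBreakdown, gradients)."""
        recon, _, pooled, cache = self._forward(params, bn_stats, batch, training, rng)
        loss = compute_loss(
            recon, batch.X, pooled, batch.targets, self.alpha, batch.cell_index,
            batch.n_target_dims,
        )
        grads = self._backward(params, batch, cache, recon, pooled)
        return loss, grads

    # -- training -----------------------------------------------------------------

    def fit(self, graphs: list[CellGraph], y=None):
        if not graphs:
            raise ValueError("cannot train on an empty graph list")
        if len(graphs) < 2:
            raise ValueError("need at least 2 cells to split train/validation")
        n_genes = graphs[0].node_features.shape[1]
        rng = np.random.default_rng(self.random_state)

        params = self._init_params(n_genes, rng)
        bn_stats = self._init_bn_stats()
        adam_m = {k: np.zeros_like(v) for k, v in params.items()}
        adam_v = {k: np.zeros_like(v) for k, v in params.items()}
        adam_t = 0
        beta1, beta2, eps = 0.9, 0.999, 1e-8

        # one 80:20 split, fixed for the whole run
        perm = rng.permutation(len(graphs))
        n_val = max(1, int(round(self.val_fraction * len(graphs))))
        n_val = min(n_val, len(graphs) - 1)
        val_idx = perm[:n_val]
        train_idx = perm[n_val:]
        bsz = min(self.batch_size, len(train_idx))
        val_batches = [
            val_idx[i : i + self.batch_size] for i in range(0, len(val_idx), self.batch_size)
        ][: self.batches_per_epoch]

        stopper = EarlyStopper(self.early_stop_min_delta, self.early_stop_patience)
        best_params = copy.deepcopy(params)
        best_bn = copy.deepcopy(bn_stats)
        history: list[dict] = []

        for epoch in range(1, self.epochs + 1):
            tr_l1 = tr_l2 = tr_tot = 0.0
            for _ in range(self.batches_per_epoch):
                idx = rng.choice(len(train_idx), size=bsz, replace=False)
                batch = batch_graphs([graphs[i] for i in train_idx[idx]], self.latent_dim)
                loss, grads = self.loss_and_grads(params, bn_stats, batch, training=True, rng=rng)
                adam_t += 1
                for k in params:
                    adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * grads[k]
                    adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * grads[k] ** 2
                    mhat = adam_m[k] / (1 - beta1**adam_t)
                    vhat = adam_v[k] / (1 - beta2**adam_t)
                    params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)
                tr_l1 += loss.reconstruction
                tr_l2 += loss.embedding
                tr_tot += loss.total
            nb = self.batches_per_epoch

            va_l1 = va_l2 = va_tot = 0.0
            for vb in val_batches:
                batch = batch_graphs([graphs[i] for i in vb], self.latent_dim)
                recon, _, pooled, _ = self._forward(params, bn_stats, batch, training=False)
                loss = compute_loss(
                    recon, batch.X, pooled, batch.targets, self.alpha, batch.cell_index,
                    batch.n_target_dims,
                )
                va_l1 += loss.reconstruction
                va_l2 += loss.embedding
                va_tot += loss.total
            nvb = len(val_batches)
            val_total = va_tot / nvb
            history.append(
                {
                    "epoch": epoch,
                    "train_recon": tr_l1 / nb, "train_embed": tr_l2 / nb, "train_total": tr_tot / nb,
                    "val_recon": va_l1 / nvb, "val_embed": va_l2 / nvb, "val_total": val_total,
                }
            )
            improved, stop = stopper.update(val_total, epoch)
            if improved:
                best_params = copy.deepcopy(params)
                best_bn = copy.deepcopy(bn_stats)
            if stop:
                break

        self.params_ = best_params
        self.bn_stats_ = best_bn
        self.history_ = history
        self.best_epoch_ = stopper.best_epoch
        self.n_epochs_run_ = len(history)
        self.n_features_in_ = n_genes
        return self

    # -- inference ----------------------------------------------------------------

    def encode(self, batch: BatchedGraphs, training: bool = False) -> np.ndarray:
        """Per-node 64-D latents H2 (evaluation mode unless ``training``)."""
        _, H2, _, _ = self._forward(self.params_, self.bn_stats_, batch, training)
        return H2

    def decode(self, H2: np.ndarray) -> np.ndarray:
        """Node-wise reconstruction from latents (evaluation mode)."""
        p = self.params_
        F1 = H2 @ p["W_d1"] + p["b_d1"]
        B3, _ = _bn_forward(
            F1, p["gamma3"], p["beta3"], self.bn_stats_["mean3"], self.bn_stats_["var3"], False
        )
        return np.maximum(B3, 0.0) @ p["W_d2"] + p["b_d2"]

    def transform(self, graphs: list[CellGraph], chunk_size: int = 256) -> np.ndarray:
        """Mean-pooled per-cell latents (cells x latent_dim), eval mode."""
        out = np.zeros((len(graphs), self.latent_dim))
        for start in range(0, len(graphs), chunk_size):
            chunk = graphs[start : start + chunk_size]
            batch = batch_graphs(chunk, self.latent_dim)
            _, _, pooled, _ = self._forward(self.params_, self.bn_stats_, batch, training=False)
            out[start : start + len(chunk)] = pooled
        return out

    # -- persistence --------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Save config, weights and batch-norm statistics to an .npz file."""
        arrays = {f"p_{k}": v for k, v in self.params_.items()}
        arrays.update({f"s_{k}": v for k, v in self.bn_stats_.items()})
        arrays["config_json"] = np.array(json.dumps(self.get_params()))
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "GraphAutoencoder":
        with np.load(path, allow_pickle=False) as data:
            model = cls(**json.loads(str(data["config_json"])))
            model.params_ = {k[2:]: data[k] for k in data.files if k.startswith("p_")}
            model.bn_stats_ = {k[2:]: data[k] for k in data.files if k.startswith("s_")}
            model.n_features_in_ = model.params_["W_g1"].shape[0]
        return model


def pool_cell(H2: np.ndarray, cell_index: np.ndarray) -> np.ndarray:
    """Mean node latents per cell: h_bar_c = (1/|V_c|) sum_{g in V_c} H2(g)."""
    C = int(cell_index.max()) + 1 if len(cell_index) else 0
    sums = np.zeros((C, H2.shape[1]))
    np.add.at(sums, cell_index, H2)
    counts = np.bincount(cell_index, minlength=C)
    return sums / counts[:, None]
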