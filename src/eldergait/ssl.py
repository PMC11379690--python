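"""Self-supervised pretext training: MTL augmentation prediction and SimCLR.

MTL: each window is pushed through the four-augmentation sampler; the model
(encoder -> head -> linear task layer) emits four logits and the loss is the
binary cross-entropy against the applied-augmentation bits, averaged over
the four tasks and the batch.

SimCLR: each window yields two rotated views; embeddings (encoder -> head
output, used directly as the feature vector) are compared by cosine
similarity and scored with the normalized temperature-scaled cross-entropy
(NT-Xent): for anchor i with positive j,

    l(i, j) = -log  exp(cos(z_i, z_j)/tau) / sum_{k != i} exp(cos(z_i, z_k)/tau)

averaged over all 2N ordered positive pairs, so each positive competes
against the 2N-2 views from other windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import (Adam, Linear, Module, Tensor, gather_rows, logsumexp_rows,
                  softplus, sqrt)
from .augment import AugmentationPolicy, apply_mtl, simclr_views
from .model_core import Encoder, HeadConfig, build_head
from .preprocess import Window


@dataclass
class SimclrConfig:
    temperature: float = 0.1
    batch_size: int = 64

    def __post_init__(self):
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")


@dataclass
class PretrainConfig:
    epochs: int = 10
    batch_size: int = 64
    learning_rate: float = 1e-3
    policy: AugmentationPolicy = field(default_factory=AugmentationPolicy)
    simclr: SimclrConfig = field(default_factory=SimclrConfig)


def mtl_loss(logits: Tensor | np.ndarray, flags: np.ndarray) -> Tensor:
    """Mean over the four pretext tasks of mean-over-batch binary CE.

    Stable form: BCE(l, y) = softplus(l) - y*l, summed symmetric in the
    mean; both means collapse to one mean over all N x 4 terms.
    """
    logits = logits if isinstance(logits, Tensor) else Tensor(logits)
    flags = np.asarray(flags, dtype=logits.data.dtype)
    if logits.shape != flags.shape:
        raise ValueError("logits and flags shapes must agree")
    if not np.all(np.isfinite(logits.data)):
        raise ValueError("non-finite logits")
    return (softplus(logits) - Tensor(flags) * logits).mean()


def _l2_normalize_rows(z: Tensor) -> Tensor:
    norms = sqrt((z * z).sum(axis=1, keepdims=True))
    if np.any(norms.data <= 1e-12):
        raise ValueError("zero-norm embedding: cosine similarity undefined")
    return z / norms


def nt_xent(z: Tensor | np.ndarray, pairing: np.ndarray,
            cfg: SimclrConfig) -> Tensor:
    """NT-Xent over 2N views; ``pairing[i]`` indexes view i's positive."""
    z = z if isinstance(z, Tensor) else Tensor(z)
    pairing = np.asarray(pairing, dtype=np.int64)
    n_views = z.shape[0]
    if n_views < 4 or n_views % 2:
        raise ValueError("need an even number of views, 2N >= 4")
    if (pairing.shape != (n_views,) or np.any(pairing == np.arange(n_views))
            or np.any(pairing[pairing] != np.arange(n_views))):
        raise ValueError("pairing must be a fixed-point-free involution")
    zn = _l2_normalize_rows(z)
    sim = (zn @ zn.T) * (1.0 / cfg.temperature)
    # exclude self-similarity from every denominator
    mask = Tensor(np.where(np.eye(n_views, dtype=bool), -1e9,
                           0.0).astype(z.data.dtype))
    denom = logsumexp_rows(sim + mask)
    pos = gather_rows(sim, pairing)
    return (denom - pos).mean()


def make_pairing(n_pairs: int) -> np.ndarray:
    """Canonical view layout [a1..aN, b1..bN]: i pairs with i +/- N."""
    return np.concatenate([np.arange(n_pairs, 2 * n_pairs),
                           np.arange(0, n_pairs)])


class MtlTaskLayer(Module):
    """Single linear map from the feature vector to the 4 augmentation logits."""

    def __init__(self, in_dim: int, seed: int = 0):
        super().__init__()
        self.linear = Linear(in_dim, 4, np.random.default_rng(seed))

    def forward(self, z: Tensor) -> Tensor:
        return self.linear(z)


@dataclass
class PretrainResult:
    encoder: Encoder
    head: Module
    task_layer: MtlTaskLayer | None
    losses: list[float]
    scheme: str


def _as_array(windows) -> np.ndarray:
    if isinstance(windows, np.ndarray):
        return windows.astype(np.float32, copy=False)
    arrs = [w.samples if isinstance(w, Window) else np.asarray(w, np.float32)
            for w in windows]
    if not arrs:
        return np.empty((0, 3, 300), np.float32)
    return np.stack(arrs).astype(np.float32)


def pretrain(windows, encoder: Encoder, head: Module, scheme: str,
             cfg: PretrainConfig | None = None, seed: int = 0,
             head_out_dim: int | None = None) -> PretrainResult:
    """Run one pretext-training schedule; returns modules + per-epoch loss.

    With a frozen encoder only the head (and, for MTL, the task layer)
    parameters change. Randomness (batch order, augmentation draws, task-head
    init) flows from ``seed`` alone.
    """
    if scheme not in ("mtl", "simclr"):
        raise ValueError("scheme must be 'mtl' or 'simclr'")
    cfg = cfg or PretrainConfig()
    x = _as_array(windows)
    if x.shape[0] == 0:
        raise ValueError("empty window set")
    rng = np.random.default_rng(seed)
    task_layer = None
    params = encoder.trainable_parameters() + head.trainable_parameters()
    if scheme == "mtl":
        if head_out_dim is None:
            head_out_dim = _infer_out_dim(head, encoder)
        task_layer = MtlTaskLayer(head_out_dim, seed=seed + 1)
        params += task_layer.trainable_parameters()
    opt = Adam(params, lr=cfg.learning_rate)
    losses: list[float] = []
    n = x.shape[0]
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            if scheme == "simclr" and idx.size < 2:
                continue
            encoder.train()
            head.train()
            if scheme == "mtl":
                batch, flags = [], []
                for i in idx:
                    w_aug, f = apply_mtl(x[i], cfg.policy, rng)
                    batch.append(w_aug)
                    flags.append(f.as_array())
                logits = task_layer(head(encoder(Tensor(np.stack(batch)))))
                loss = mtl_loss(logits, np.stack(flags))
            else:
                views_a, views_b = [], []
                for i in idx:
                    va, vb = simclr_views(x[i], cfg.policy, rng)
                    views_a.append(va)
                    views_b.append(vb)
                batch = np.stack(views_a + views_b)
                z = head(encoder(Tensor(batch)))
                loss = nt_xent(z, make_pairing(idx.size), cfg.simclr)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        losses.append(float(np.mean(epoch_losses)))
    return PretrainResult(encoder=encoder, head=head, task_layer=task_layer,
                          losses=losses, scheme=scheme)


def _infer_out_dim(head: Module, encoder: Encoder) -> int:
    from ._nn import no_grad
    probe = Tensor(np.zeros((1, encoder.config.feature_dim), np.float32))
    head.eval()
    with no_grad():
        return int(head(probe).shape[1])
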