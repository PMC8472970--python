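"""Loss, optimization schedule and the patch-based training loop.

Training follows the patch protocol: random 48x48 crops are drawn once
from every training image, shuffled, and fed through the network in
mini-batches under pixelwise binary cross-entropy.  Adam drives the
updates (first-moment decay 0.9, L2 weight decay 5e-4) and a step-decay
schedule multiplies the learning rate by ``1 - step_decay`` every
``decay_interval`` epochs (coefficient 0.01 by default).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, replace

import numpy as np

from .nn import Adam
from .patching import PatchSpec, sample_patches
from .synthvessel import derive_seed

__all__ = ["TrainConfig", "bce_loss", "train"]

EPS = 1e-7


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    The benchmark-scale protocol uses 200 epochs at batch size 256 with
    10,480 patches per image; desk-scale runs shrink epochs and patch
    counts, not the learning dynamics.
    """

    epochs: int = 200
    batch_size: int = 256
    lr: float = 1e-3
    beta1: float = 0.9
    step_decay: float = 0.01
    decay_interval: int = 1
    weight_decay: float = 5e-4
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.decay_interval < 1:
            raise ValueError("epochs, batch_size and decay_interval must be >= 1")
        if self.lr < 0 or self.step_decay < 0 or self.weight_decay < 0:
            raise ValueError("rates must be non-negative")
        if self.device != "cpu":
            raise ValueError("only cpu execution is supported")


def bce_loss(y: np.ndarray, yhat: np.ndarray) -> float:
    """Pixel-averaged binary cross-entropy, in nats.

    ``-mean(y log p + (1 - y) log(1 - p))`` with predictions clipped to
    ``[1e-7, 1 - 1e-7]`` so the loss stays finite.
    """
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: labels {y.shape}, predictions {yhat.shape}")
    p = np.clip(yhat, EPS, 1.0 - EPS)
    return float(-(y * np.log(p) + (1.0 - y) * np.log1p(-p)).mean())


def train(net, dataset, train_config: TrainConfig, patch_spec: PatchSpec,
          log_fn=None):
    """Train ``net`` in place on ``dataset`` and return ``(net, history)``.

    ``dataset`` is a list of ``(image, label, mask)`` triples (2-D
    arrays).  Patches are sampled once per image with seeds derived from
    ``patch_spec.seed``; the epoch shuffle uses ``train_config.seed``.
    ``history`` is a list of per-epoch dicts (mean loss, lr, timing).
    """
    if not dataset:
        raise ValueError("training set is empty")
    images, labels = [], []
    for i, (img, lab, msk) in enumerate(dataset):
        pset = sample_patches(img, lab, msk,
                              replace(patch_spec, seed=derive_seed(patch_spec.seed, i)))
        images.append(pset.images)
        labels.append(pset.labels)
    x = np.concatenate(images, axis=0)
    y = np.concatenate(labels, axis=0)

    rng = np.random.default_rng(train_config.seed)
    opt = Adam(net.parameters(), lr=train_config.lr, beta1=train_config.beta1,
               weight_decay=train_config.weight_decay)
    history = []
    net.train()
    for epoch in range(train_config.epochs):
        opt.lr = train_config.lr * (
            (1.0 - train_config.step_decay) ** (epoch // train_config.decay_interval))
        order = rng.permutation(len(x))
        t0 = time.time()
        losses = []
        for start in range(0, len(order), train_config.batch_size):
            idx = order[start:start + train_config.batch_size]
            xb, yb = x[idx], y[idx]
            p = net.forward(xb)
            losses.append(bce_loss(yb, p))
            net.zero_grad()
            net.backward(((p - yb) / p.size).astype(p.dtype))
            opt.step()
        entry = {"epoch": epoch, "loss": float(np.mean(losses)),
                 "lr": opt.lr, "seconds": time.time() - t0}
        history.append(entry)
        if log_fn is not None:
            log_fn(entry)
    return net, history
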