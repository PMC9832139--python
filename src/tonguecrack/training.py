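"""Two-phase training of the crack network.

Phase one trains the segmentation network alone with a per-cell binary
cross-entropy between the sigmoid of the 1/8-resolution logit map and the
max-pooled ground-truth mask.  Phase two trains the decision network on
image-level labels while the segmentation weights stay frozen (bit
identical); because they are frozen, segmentation outputs are computed once
per sample and cached.

Both phases use plain SGD (learning rate 0.005, no momentum, no schedule),
batch size 2, a constant multiplier of 0.1 on the cross-entropy loss, and a
class-alternating sampler: even iterations draw cracked images, odd
iterations non-cracked ones, so both classes are visited at a constant
rate regardless of the class imbalance in the training set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .sbdl import DecNet, SegNet, init_params
from .synthdata import CRACKED, NON_CRACKED

__all__ = [
    "TrainConfig",
    "downsample_mask",
    "class_scheduler",
    "train_segnet",
    "train_decnet",
]


@dataclass
class TrainConfig:
    """Hyper-parameters of both training phases.

    ``loss_weight`` is a constant multiplier on the cross-entropy loss
    (equivalent to scaling the learning rate, but exposed separately so the
    published setting — learning rate 0.005 together with a loss factor of
    0.1 — can be stated as such).  ``epochs_seg`` / ``epochs_dec`` are
    iteration budgets: one iteration is one SGD step on one batch.
    ``loss`` selects the segmentation criterion: ``"bce"`` (default) or a
    per-pixel ``"mse"`` between the sigmoid map and the target.
    """

    learning_rate: float = 0.005
    loss_weight: float = 0.1
    batch_size: int = 2
    epochs_seg: int = 500
    epochs_dec: int = 500
    seed: int = 0
    loss: str = "bce"

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError(f"learning_rate must be >= 0, got {self.learning_rate}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.loss not in ("bce", "mse"):
            raise ValueError(f"loss must be 'bce' or 'mse', got {self.loss!r}")


def downsample_mask(mask: np.ndarray, factor: int = 8) -> np.ndarray:
    """Max-pool a binary mask by ``factor``: an output cell is 1 iff any
    pixel of its ``factor x factor`` block is 1 (the training target for
    the 1/8-resolution logit map)."""
    mask = np.asarray(mask)
    h, w = mask.shape
    for name, size in (("height", h), ("width", w)):
        if size % factor != 0:
            raise ValueError(
                f"mask {name} {size} is not divisible by factor {factor}"
            )
    blocks = mask.reshape(h // factor, factor, w // factor, factor)
    return (blocks.max(axis=(1, 3)) > 0).astype(np.uint8)


def class_scheduler(iteration: int) -> str:
    """Class drawn at an iteration: cracked when even, non-cracked when
    odd, so classes alternate at a constant rate."""
    return CRACKED if iteration % 2 == 0 else NON_CRACKED


def _seg_loss_grad(logits, targets, config):
    """Loss value and gradient w.r.t. the logit map (mean reduction over
    every cell of the batch, scaled by ``loss_weight``)."""
    p = nn.sigmoid(logits)
    n = logits.size
    t = targets
    if config.loss == "bce":
        eps = 1e-12
        loss = -np.mean(t * np.log(p + eps) + (1.0 - t) * np.log(1.0 - p + eps))
        dlogits = (p - t) / n
    else:  # per-pixel MSE on the probability map
        loss = np.mean((p - t) ** 2)
        dlogits = 2.0 * (p - t) * p * (1.0 - p) / n
    w = config.loss_weight
    return w * float(loss), (w * dlogits).astype(np.float32)


def _bce_logit_grad(logits, labels, weight):
    p = nn.sigmoid(logits)
    eps = 1e-12
    loss = -np.mean(labels * np.log(p + eps) + (1.0 - labels) * np.log(1.0 - p + eps))
    dlogits = (p - labels) / logits.size
    return weight * float(loss), (weight * dlogits).astype(np.float32)


def _index_pools(samples):
    pos = [i for i, s in enumerate(samples) if s.label == CRACKED]
    neg = [i for i, s in enumerate(samples) if s.label == NON_CRACKED]
    if not pos or not neg:
        raise ValueError(
            "training requires at least one cracked and one non-cracked "
            f"sample (got {len(pos)} cracked, {len(neg)} non-cracked)"
        )
    return {CRACKED: np.array(pos), NON_CRACKED: np.array(neg)}


def train_segnet(samples, config: TrainConfig, params: SegNet | None = None,
                 callback=None) -> SegNet:
    """Train the segmentation network on samples with ground-truth masks.

    Every sample must carry a mask (empty for non-cracked images) and both
    classes must be present.  Returns the trained network with its loss
    trace attached as ``params.train_loss``.  Deterministic for a fixed
    config and sample list.
    """
    samples = list(samples)
    for i, s in enumerate(samples):
        if s.mask is None:
            raise ValueError(f"sample {i} has no ground-truth mask")
    pools = _index_pools(samples)
    seg = params if params is not None else init_params(config.seed)[0]

    images = [s.image.astype(np.float32) / 255.0 for s in samples]
    targets = [
        downsample_mask(s.mask).astype(np.float32)[:, :, None] for s in samples
    ]
    rng = np.random.default_rng([int(config.seed), 0x5E6])
    opt = nn.SGD([seg], config.learning_rate)
    history = []
    for it in range(config.epochs_seg):
        pool = pools[class_scheduler(it)]
        idx = rng.choice(pool, size=config.batch_size, replace=True)
        x = np.stack([images[i] for i in idx])
        t = np.stack([targets[i] for i in idx])
        logits, _ = seg.forward(x, train=True)
        loss, dlogits = _seg_loss_grad(logits, t, config)
        seg.backward(dlogits)
        opt.step()
        history.append(loss)
        if callback is not None:
            callback(it, loss)
    seg.train_loss = history
    return seg


def train_decnet(samples, seg_params: SegNet, config: TrainConfig,
                 params: DecNet | None = None, callback=None) -> DecNet:
    """Train the decision network with the segmentation weights frozen.

    ``seg_params`` is used in evaluation mode only and is never modified
    (its outputs per sample are computed once and cached).  Returns the
    trained decision network with ``params.train_loss`` attached.
    """
    samples = list(samples)
    pools = _index_pools(samples)
    dec = params if params is not None else init_params(config.seed)[1]

    feats, logit_maps = [], []
    for s in samples:
        x = s.image.astype(np.float32)[None] / 255.0
        logits, f = seg_params.forward(x, train=False)
        logit_maps.append(logits[0])
        feats.append(f[0])
    labels = np.array(
        [1.0 if s.label == CRACKED else 0.0 for s in samples], dtype=np.float64
    )

    rng = np.random.default_rng([int(config.seed), 0xDEC])
    opt = nn.SGD([dec], config.learning_rate)
    history = []
    for it in range(config.epochs_dec):
        pool = pools[class_scheduler(it)]
        idx = rng.choice(pool, size=config.batch_size, replace=True)
        f = np.stack([feats[i] for i in idx])
        lm = np.stack([logit_maps[i] for i in idx])
        y = labels[idx][:, None]
        out = dec.forward(f, lm, train=True)
        loss, dout = _bce_logit_grad(out, y, config.loss_weight)
        dec.backward(dout)
        opt.step()
        history.append(loss)
        if callback is not None:
            callback(it, loss)
    dec.train_loss = history
    return dec
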