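"""Training-set augmentation: impulse noise, gamma contrast, mirroring.

These are the three operators used to expand the cracked training images
(141 originals -> 564 training positives: each original contributes itself
plus one noisy, one contrast-adjusted and one mirrored copy).  Noise and
contrast adjustment touch the image only — they never create or destroy
crack ground truth — while mirroring applies the same column permutation to
image and mask.
"""

from __future__ import annotations

import numpy as np

from .synthdata import TongueSample

__all__ = [
    "DEFAULT_SP_FRACTION",
    "DEFAULT_GAMMA",
    "salt_pepper",
    "adjust_contrast",
    "hmirror",
    "expand_positives",
]

DEFAULT_SP_FRACTION = 0.01
DEFAULT_GAMMA = 0.8


def salt_pepper(image: np.ndarray, fraction: float, seed: int) -> np.ndarray:
    """Set ``round(fraction * H * W)`` random pixel positions (chosen
    without replacement) to pure black or pure white across all channels.

    Salt and pepper are equally likely; all other pixels are unchanged.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    h, w = image.shape[:2]
    n = int(np.floor(fraction * h * w + 0.5))
    out = np.array(image, copy=True)
    if n == 0:
        return out
    rng = np.random.default_rng(int(seed))
    positions = rng.choice(h * w, size=n, replace=False)
    values = rng.integers(0, 2, size=n).astype(image.dtype) * 255
    flat = out.reshape(h * w, -1)
    flat[positions, :] = values[:, None]
    return out


def adjust_contrast(image: np.ndarray, gamma: float) -> np.ndarray:
    """Per-channel gamma transform ``out = 255 (in/255)^gamma``, rounded
    half-up and clipped to [0, 255].  ``gamma < 1`` brightens mid-tones,
    ``gamma > 1`` darkens them; 255 is a fixed point for any gamma."""
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    x = image.astype(np.float64) / 255.0
    out = np.clip(np.floor(255.0 * np.power(x, gamma) + 0.5), 0, 255)
    return out.astype(np.uint8)


def hmirror(sample: TongueSample) -> TongueSample:
    """Mirror image and mask around the vertical centre axis (an
    involution; the label is unchanged)."""
    mask = None if sample.mask is None else np.ascontiguousarray(sample.mask[:, ::-1])
    return TongueSample(
        image=np.ascontiguousarray(sample.image[:, ::-1, :]),
        mask=mask,
        label=sample.label,
        meta={"augment": "hmirror", "source_seed": sample.meta.get("seed")},
    )


def _with_image(sample, image, op):
    return TongueSample(
        image=image,
        mask=None if sample.mask is None else sample.mask.copy(),
        label=sample.label,
        meta={"augment": op, "source_seed": sample.meta.get("seed")},
    )


def expand_positives(
    positives,
    seed: int,
    sp_fraction: float = DEFAULT_SP_FRACTION,
    gamma: float = DEFAULT_GAMMA,
):
    """Expand cracked training samples fourfold.

    Returns the originals followed by one salt-and-pepper copy, one
    contrast-adjusted copy and one mirrored copy of each, in that order:
    ``len(result) == 4 * len(positives)`` always.  Only cracked samples are
    expanded this way; callers pass negatives through untouched.
    """
    positives = list(positives)
    rng = np.random.default_rng(int(seed))
    noise_seeds = rng.integers(0, 2**31, size=len(positives))
    out = list(positives)
    out.extend(
        _with_image(s, salt_pepper(s.image, sp_fraction, int(ns)), "salt_pepper")
        for s, ns in zip(positives, noise_seeds)
    )
    out.extend(
        _with_image(s, adjust_contrast(s.image, gamma), "contrast")
        for s in positives
    )
    out.extend(hmirror(s) for s in positives)
    return out
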