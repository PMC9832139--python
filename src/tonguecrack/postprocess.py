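"""From a 1/8-resolution logit map to a full-resolution mask and skeleton.

The raw network output is a coarse logit map.  It is turned into the final
crack extraction in three steps, all at full image resolution: sigmoid +
threshold + nearest-neighbour upsampling, one binary erosion with a full
3x3 rectangular structuring element (removes one-cell speckle and thins the
blocky upsampled boundary), and two-subiteration morphological thinning to
the one-pixel-wide, 8-connected crack skeleton.  Area-based quantities
downstream (segmentation metrics, crack indices) use the eroded mask; the
skeleton is a degenerate-area centreline kept for crack-shape inspection.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.morphology import thin as _thin

from . import nn

__all__ = [
    "binarize_and_upsample",
    "erode3x3",
    "thin_to_skeleton",
    "postprocess_pipeline",
]

_UPSAMPLE = 8
_SE3 = np.ones((3, 3), dtype=bool)


def binarize_and_upsample(logit_map, threshold: float = 0.5, out_size=None):
    """Sigmoid, strict ``>`` threshold, then 8x nearest-neighbour upsample.

    ``out_size`` defaults to exactly 8x the logit-map shape and is rejected
    otherwise (a logit of 0 at threshold 0.5 is negative: strict
    comparison).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    logit_map = np.asarray(logit_map)
    h, w = logit_map.shape
    expected = (h * _UPSAMPLE, w * _UPSAMPLE)
    if out_size is None:
        out_size = expected
    if tuple(out_size) != expected:
        raise ValueError(
            f"out_size {tuple(out_size)} is not {_UPSAMPLE}x the logit map "
            f"shape {(h, w)} (expected {expected})"
        )
    binary = nn.sigmoid(logit_map) > threshold
    up = np.repeat(np.repeat(binary, _UPSAMPLE, axis=0), _UPSAMPLE, axis=1)
    return up.astype(np.uint8)


def erode3x3(mask) -> np.ndarray:
    """Binary erosion with a full 3x3 rectangular template; neighbours
    outside the image count as background."""
    mask = np.asarray(mask) > 0
    return ndimage.binary_erosion(mask, structure=_SE3, border_value=0).astype(
        np.uint8
    )


def thin_to_skeleton(mask) -> np.ndarray:
    """Iterative two-subiteration thinning to a 1-pixel-wide, 8-connected
    skeleton; a subset of the input with the same connected components."""
    mask = np.asarray(mask) > 0
    return _thin(mask).astype(np.uint8)


def postprocess_pipeline(logit_map, threshold: float = 0.5, out_size=None):
    """binarize_and_upsample -> erode3x3 -> thin_to_skeleton.

    Returns ``(mask, skeleton)``: the eroded full-resolution mask (used for
    areas and indices) and its skeleton.
    """
    up = binarize_and_upsample(logit_map, threshold=threshold, out_size=out_size)
    mask = erode3x3(up)
    skeleton = thin_to_skeleton(mask)
    return mask, skeleton
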