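"""TCM crack quantification: visible index (FCI) and depth index (FDI).

Traditional Chinese Medicine describes tongue cracks by how many there are
(single / double / multiple cracks) and how deep they run.  Two
dimensionless indices quantify this from a crack mask over a tongue crop:

* visible index   FCI = k_v * S_t / S_f, where S_t is the crack-area pixel
  count and S_f the non-crack-area pixel count — larger means more or
  longer cracks (0 for a crack-free tongue);
* depth index     FDI = k_d * (G_f / G_t - 1), where G_f and G_t are the
  mean gray levels of the non-crack and crack areas — deeper cracks are
  darker, so larger means deeper (0 for a crack-free tongue, by
  convention, since G_t is undefined there).

The published constants are k_v = 10 and k_d = 2.  Inputs are pre-cropped
tongue patches, so the whole image is the default evaluation region; an
optional region mask restricts both areas (e.g. to the tongue proper).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["IndexConfig", "CrackIndices", "to_gray", "compute_fci", "compute_fdi", "compute_indices"]


@dataclass(frozen=True)
class IndexConfig:
    """Constant factors of the two indices (published values 10 and 2)."""

    k_v: float = 10.0
    k_d: float = 2.0

    def __post_init__(self):
        if self.k_v <= 0 or self.k_d <= 0:
            raise ValueError("index constants k_v and k_d must be positive")


@dataclass(frozen=True)
class CrackIndices:
    """The (FCI, FDI) pair for one image."""

    FCI: float
    FDI: float


DEFAULT_CONFIG = IndexConfig()


def to_gray(image: np.ndarray) -> np.ndarray:
    """Luma gray level Y = 0.299 R + 0.587 G + 0.114 B, real valued."""
    image = np.asarray(image, dtype=np.float64)
    return image[..., 0] * 0.299 + image[..., 1] * 0.587 + image[..., 2] * 0.114


def _prepare_masks(crack_mask, region_mask):
    crack = np.asarray(crack_mask) > 0
    if region_mask is None:
        region = np.ones_like(crack, dtype=bool)
    else:
        region = np.asarray(region_mask) > 0
        if region.shape != crack.shape:
            raise ValueError(
                f"region mask shape {region.shape} does not match crack mask "
                f"shape {crack.shape}"
            )
        if np.any(crack & ~region):
            raise ValueError("crack mask must be contained in the region mask")
    return crack, region


def compute_fci(crack_mask, region_mask=None, config: IndexConfig = DEFAULT_CONFIG) -> float:
    """Visible index ``k_v * S_t / S_f``; exactly 0 for an empty crack mask."""
    crack, region = _prepare_masks(crack_mask, region_mask)
    s_t = int(np.count_nonzero(crack))
    s_f = int(np.count_nonzero(region)) - s_t
    if s_f == 0:
        raise ValueError("non-crack area is empty; FCI is undefined")
    return config.k_v * s_t / s_f


def compute_fdi(image, crack_mask, region_mask=None, config: IndexConfig = DEFAULT_CONFIG) -> float:
    """Depth index ``k_d * (G_f / G_t - 1)``; 0 for an empty crack mask."""
    crack, region = _prepare_masks(crack_mask, region_mask)
    if not crack.any():
        return 0.0
    gray = to_gray(image)
    if gray.shape != crack.shape:
        raise ValueError(
            f"image spatial shape {gray.shape} does not match crack mask "
            f"shape {crack.shape}"
        )
    g_t = float(gray[crack].mean())
    noncrack = region & ~crack
    if not noncrack.any():
        raise ValueError("non-crack area is empty; FDI is undefined")
    g_f = float(gray[noncrack].mean())
    if g_t == 0.0:
        raise ValueError("crack area is pure black; FDI is undefined")
    return config.k_d * (g_f / g_t - 1.0)


def compute_indices(image, crack_mask, region_mask=None,
                    config: IndexConfig = DEFAULT_CONFIG) -> CrackIndices:
    """Both indices for one image and crack mask."""
    return CrackIndices(
        FCI=compute_fci(crack_mask, region_mask, config),
        FDI=compute_fdi(image, crack_mask, region_mask, config),
    )
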