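"""From a coarse logit map to a crack mask, skeleton and TCM indices.

Builds a noisy 1/8-resolution logit map directly from a synthetic crack's
ground truth (standing in for a trained segmentation network), then runs
the post-processing chain — sigmoid + threshold, 8x nearest-neighbour
upsampling, 3x3 erosion, thinning — and quantifies the result with the
visible index (FCI, crack area relative to the rest) and the depth index
(FDI, relative darkness of crack pixels).
"""

import numpy as np

from tonguecrack import (
    SynthConfig,
    compute_fdi,
    compute_fci,
    downsample_mask,
    postprocess_pipeline,
    render_sample,
)

sample = render_sample(SynthConfig(image_size=128, contrast_gap=40.0, seed=3), seed=9)
cells = downsample_mask(sample.mask)

rng = np.random.default_rng(0)
logits = np.where(cells > 0, 4.0, -4.0) + rng.normal(scale=1.0, size=cells.shape)

mask, skeleton = postprocess_pipeline(logits, threshold=0.5)
print(f"logit map {logits.shape} -> mask {mask.shape}")
print(f"crack pixels: ground truth {sample.mask.sum()}, extracted {mask.sum()}, skeleton {skeleton.sum()}")

fci = compute_fci(mask)
fdi = compute_fdi(sample.image, mask)
print(f"FCI = {fci:.4f}  (k_v * crack area / non-crack area; 0 means no crack)")
print(f"FDI = {fdi:.4f}  (k_d * (G_f/G_t - 1); positive because cracks are darker)")
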