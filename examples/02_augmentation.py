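"""The three augmentation operators and the fourfold positive expansion.

Cracked training images are expanded 4x (original + salt-and-pepper copy +
gamma-contrast copy + mirrored copy); with the published cohort this takes
the 141 cracked training images to 564.
"""

import numpy as np

from tonguecrack import SynthConfig, expand_positives, generate_dataset

config = SynthConfig(image_size=64, contrast_gap=60.0, seed=0)
positives = generate_dataset(n_pos=141, n_neg=0, config=config, seed=7)
expanded = expand_positives(positives, seed=0)

print(f"{len(positives)} cracked originals -> {len(expanded)} training positives")

n = len(positives)
orig, noisy, contrast, mirrored = (
    expanded[0], expanded[n], expanded[2 * n], expanded[3 * n]
)
changed = (noisy.image != orig.image).any(axis=2).mean()
print(f"salt-and-pepper copy: {changed:.1%} of pixels corrupted")
print(f"contrast copy: mean gray {orig.image.mean():.1f} -> {contrast.image.mean():.1f} (gamma 0.8 brightens)")
print(f"mirrored copy: mask preserved under mirroring: {np.array_equal(mirrored.mask, orig.mask[:, ::-1])}")
print(f"masks untouched by noise/contrast: {np.array_equal(noisy.mask, orig.mask)}")
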