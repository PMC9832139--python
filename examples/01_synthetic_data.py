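"""Generate synthetic tongue crops with exact crack ground truth.

Each sample is a reddish tongue-textured crop with 1-3 dark zigzag crack
strips of varying width, plus distractors (bright papillae dots, a darker
contour ring) that are deliberately excluded from the mask.
"""

from tonguecrack import SynthConfig, generate_dataset, to_gray

config = SynthConfig(image_size=128, contrast_gap=25.0, seed=0)
samples = generate_dataset(n_pos=4, n_neg=2, config=config, seed=42)

print(f"{len(samples)} samples ({config.image_size}x{config.image_size})")
for i, s in enumerate(samples):
    gray = to_gray(s.image)
    if s.mask.any():
        gap = gray[s.mask == 0].mean() - gray[s.mask > 0].mean()
        note = f"{int(s.mask.sum()):5d} crack px, crack darker by {gap:4.1f} gray levels"
    else:
        note = "    0 crack px"
    print(f"  sample {i}: {s.label:12s} {note}")

# The crack/background contrast printed above hovers around the configured
# contrast_gap (25): low contrast is what makes the real task hard.
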