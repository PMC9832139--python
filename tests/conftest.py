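import numpy as np
import pytest

from tonguecrack import SynthConfig, TongueSample, generate_dataset, render_sample

# High-contrast, small crops keep the CNN tests fast while preserving the
# geometry of the full-size task (cracks span the crop, papillae distract).
SMALL = dict(image_size=64, contrast_gap=60.0, papillae_density=10, seed=0)


@pytest.fixture(scope="session")
def small_cfg():
    return SynthConfig(**SMALL)


@pytest.fixture(scope="session")
def pos_sample(small_cfg):
    sample = render_sample(small_cfg, 1)
    assert sample.label == "cracked"
    return sample


@pytest.fixture(scope="session")
def tiny_dataset(small_cfg):
    """4 cracked + 4 non-cracked 64x64 crops."""
    return generate_dataset(4, 4, small_cfg, 3)


def make_dummy_samples(n_pos, n_neg, size=8):
    """Lightweight labelled samples for split/augment arithmetic tests."""
    pos_mask = np.zeros((size, size), np.uint8)
    pos_mask[size // 2, size // 2] = 1
    image = np.full((size, size, 3), 128, np.uint8)
    out = [
        TongueSample(image=image.copy(), mask=pos_mask.copy(), label="cracked")
        for _ in range(n_pos)
    ]
    out += [
        TongueSample(
            image=image.copy(),
            mask=np.zeros((size, size), np.uint8),
            label="non-cracked",
        )
        for _ in range(n_neg)
    ]
    return out
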