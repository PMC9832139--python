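"""Dataset layout on disk: PNG images, 0/255 PNG masks, labels.csv."""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .synthdata import CRACKED, NON_CRACKED, TongueSample

__all__ = ["save_dataset", "load_dataset", "save_mask", "load_mask"]


def save_mask(path, mask) -> None:
    iio.imwrite(path, (np.asarray(mask) > 0).astype(np.uint8) * 255)


def load_mask(path) -> np.ndarray:
    mask = iio.imread(path)
    if mask.ndim == 3:
        mask = mask[..., 0]
    return (mask > 127).astype(np.uint8)


def save_dataset(directory, samples) -> None:
    """Write ``images/*.png``, ``masks/*.png`` (only for samples that have
    one) and ``labels.csv`` (filename,label)."""
    directory = str(directory)
    os.makedirs(os.path.join(directory, "images"), exist_ok=True)
    os.makedirs(os.path.join(directory, "masks"), exist_ok=True)
    rows = []
    for i, sample in enumerate(samples):
        name = f"{i:05d}.png"
        iio.imwrite(os.path.join(directory, "images", name), sample.image)
        if sample.mask is not None:
            save_mask(os.path.join(directory, "masks", name), sample.mask)
        rows.append({"filename": name, "label": sample.label})
    pd.DataFrame(rows).to_csv(os.path.join(directory, "labels.csv"), index=False)


def load_dataset(directory):
    """Read a dataset written by :func:`save_dataset`."""
    directory = str(directory)
    table = pd.read_csv(os.path.join(directory, "labels.csv"))
    samples = []
    for row in table.itertuples():
        image = iio.imread(os.path.join(directory, "images", row.filename))
        mask_path = os.path.join(directory, "masks", row.filename)
        mask = load_mask(mask_path) if os.path.exists(mask_path) else None
        label = row.label
        if label not in (CRACKED, NON_CRACKED):
            raise ValueError(f"unknown label {label!r} in labels.csv")
        samples.append(TongueSample(image=image, mask=mask, label=label))
    return samples
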