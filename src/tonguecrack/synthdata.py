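"""Seeded synthetic tongue-crop images with exact crack ground truth.

Clinical tongue-crack images are not publicly available, so every stage of
the pipeline is exercised on synthetic crops that reproduce the features
that make the real task hard:

* cracks are dark zigzag strips whose width varies along the crack
  (a random polyline with per-vertex half-widths, linearly interpolated
  along each segment);
* crack-to-background contrast is low (a configurable mean gray decrement,
  default 25 of 255);
* the background is a smooth, reddish low-frequency intensity field with
  fine speckle, mimicking tongue texture;
* distractors that a good model must reject are present but *excluded from
  the ground-truth mask*: bright papillae dots and a darker tongue-contour
  ring near the border.

Everything is driven by ``numpy.random.default_rng`` seeded from
``(config.seed, sample seed)``, so identical inputs regenerate
byte-identical samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CRACKED",
    "NON_CRACKED",
    "SynthConfig",
    "TongueSample",
    "render_sample",
    "generate_dataset",
]

CRACKED = "cracked"
NON_CRACKED = "non-cracked"

_BASE_GRAY = 150.0  # mean background luma, 8-bit scale
_RGB_OFFSETS = (35.0, -5.0, -15.0)  # reddish palette around the luma field


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters for one synthetic tongue crop.

    Parameters
    ----------
    image_size : int
        Pixels per side (square crops; the clinical protocol uses 400).
    n_cracks : tuple[int, int] | int
        Inclusive range for the number of cracks; ``(0, 0)`` for negatives.
    width_range : tuple[float, float]
        Bounds for the per-vertex crack half-width, in pixels.
    contrast_gap : float
        Mean gray decrement of crack pixels relative to the local
        background, in 8-bit gray levels.
    papillae_density : int
        Number of small bright distractor dots per image.
    contour_ring : bool
        Draw a darker elliptical tongue-boundary ring near the border.
    seed : int
        Mixed with the per-sample seed for reproducibility.
    """

    image_size: int = 400
    n_cracks: tuple = (1, 3)
    width_range: tuple = (1.0, 4.0)
    contrast_gap: float = 25.0
    papillae_density: int = 40
    contour_ring: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 64:
            raise ValueError(
                f"image_size must be at least 64, got {self.image_size}"
            )
        n = self.n_cracks
        if np.isscalar(n):
            n = (int(n), int(n))
        n = (int(n[0]), int(n[1]))
        if not (0 <= n[0] <= n[1]):
            raise ValueError(f"invalid n_cracks range {n}")
        object.__setattr__(self, "n_cracks", n)
        w = (float(self.width_range[0]), float(self.width_range[1]))
        if not (1.0 <= w[0] <= w[1]):
            raise ValueError(
                f"width_range minimum must be >= 1 pixel, got {w}"
            )
        object.__setattr__(self, "width_range", w)
        if self.contrast_gap <= 0:
            raise ValueError(f"contrast_gap must be positive, got {self.contrast_gap}")


@dataclass
class TongueSample:
    """An RGB tongue crop, optional binary crack mask, and image label.

    The invariant ``label == "cracked" iff mask has a positive pixel`` is
    checked whenever a mask is present.  Coordinates are row-major with the
    origin at the top-left, 0-based.
    """

    image: np.ndarray
    mask: np.ndarray | None = None
    label: str = NON_CRACKED
    meta: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if self.label not in (CRACKED, NON_CRACKED):
            raise ValueError(f"unknown label {self.label!r}")
        if self.mask is not None:
            if self.mask.shape != self.image.shape[:2]:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match image "
                    f"shape {self.image.shape[:2]}"
                )
            has_crack = bool(np.any(self.mask))
            if has_crack != (self.label == CRACKED):
                raise ValueError(
                    f"label {self.label!r} inconsistent with mask "
                    f"({int(np.count_nonzero(self.mask))} positive pixels)"
                )


def _zigzag_polyline(rng, size, n_vertices):
    """Random zigzag polyline inside a safety margin of the crop."""
    lo, hi = 0.12 * size, 0.88 * size
    p = np.array([rng.uniform(lo, hi), rng.uniform(lo, hi)])
    theta = rng.uniform(0.0, 2.0 * np.pi)
    pts = [p.copy()]
    sign = rng.choice([-1.0, 1.0])
    for _ in range(n_vertices - 1):
        step = rng.uniform(0.06, 0.16) * size
        p = p + step * np.array([np.sin(theta), np.cos(theta)])
        p = np.clip(p, lo, hi)
        pts.append(p.copy())
        # alternating turns produce the zigzag; magnitude is random
        theta += sign * rng.uniform(np.deg2rad(25.0), np.deg2rad(75.0))
        sign = -sign
    return np.array(pts)


def _stamp_strip(mask, p0, p1, w0, w1):
    """Mark pixels within the linearly interpolated half-width of segment
    p0-p1 (a strip with round caps, width varying along the segment)."""
    size = mask.shape[0]
    wmax = max(w0, w1)
    r0 = max(int(np.floor(min(p0[0], p1[0]) - wmax - 1)), 0)
    r1 = min(int(np.ceil(max(p0[0], p1[0]) + wmax + 1)) + 1, size)
    c0 = max(int(np.floor(min(p0[1], p1[1]) - wmax - 1)), 0)
    c1 = min(int(np.ceil(max(p0[1], p1[1]) + wmax + 1)) + 1, size)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d = p1 - p0
    dd = float(d @ d)
    if dd == 0.0:
        t = np.zeros_like(rr, dtype=float)
    else:
        t = ((rr - p0[0]) * d[0] + (cc - p0[1]) * d[1]) / dd
        t = np.clip(t, 0.0, 1.0)
    proj_r = p0[0] + t * d[0]
    proj_c = p0[1] + t * d[1]
    dist = np.hypot(rr - proj_r, cc - proj_c)
    halfw = w0 + t * (w1 - w0)
    mask[r0:r1, c0:c1] |= dist <= halfw


def render_sample(config: SynthConfig, seed: int) -> TongueSample:
    """Render one synthetic tongue crop with its exact crack mask.

    The returned sample's ``meta`` records the crack polylines, their
    per-vertex half-widths and arc lengths (useful for geometry checks).
    """
    size = config.image_size
    rng = np.random.default_rng([int(config.seed), int(seed)])

    # smooth low-frequency luma field: 2-4 random 2-D cosines
    yy, xx = np.mgrid[0:size, 0:size] / float(size)
    luma = np.full((size, size), _BASE_GRAY)
    for _ in range(rng.integers(2, 5)):
        fy, fx = rng.uniform(-2.5, 2.5, size=2)
        amp = rng.uniform(5.0, 12.0)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        luma += amp * np.cos(2.0 * np.pi * (fy * yy + fx * xx) + phase)
    luma += rng.normal(0.0, 3.0, size=(size, size))  # fine speckle

    image = luma[:, :, None] + np.array(_RGB_OFFSETS)

    if config.contour_ring:
        cy = cx = (size - 1) / 2.0
        ry, rx = 0.48 * size, 0.46 * size
        rad = np.sqrt(((yy * size - cy) / ry) ** 2 + ((xx * size - cx) / rx) ** 2)
        ring = np.exp(-0.5 * ((rad - 1.0) / 0.015) ** 2)
        image -= 22.0 * ring[:, :, None]

    n_pap = int(config.papillae_density)
    if n_pap:
        centers = rng.uniform(2.0, size - 2.0, size=(n_pap, 2))
        radii = rng.uniform(0.8, 2.0, size=n_pap)
        gains = rng.uniform(15.0, 30.0, size=n_pap)
        for (pr, pc), prad, gain in zip(centers, radii, gains):
            r0, r1 = int(pr - prad - 1), int(pr + prad + 2)
            c0, c1 = int(pc - prad - 1), int(pc + prad + 2)
            r0, c0 = max(r0, 0), max(c0, 0)
            r1, c1 = min(r1, size), min(c1, size)
            gr, gc = np.mgrid[r0:r1, c0:c1]
            dot = np.hypot(gr - pr, gc - pc) <= prad
            image[r0:r1, c0:c1][dot] += gain

    mask = np.zeros((size, size), dtype=bool)
    lo, hi = config.n_cracks
    n_cracks = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
    polylines, halfwidths, lengths = [], [], []
    for _ in range(n_cracks):
        n_vertices = int(rng.integers(4, 11))
        pts = _zigzag_polyline(rng, size, n_vertices)
        hws = rng.uniform(*config.width_range, size=n_vertices)
        for i in range(n_vertices - 1):
            _stamp_strip(mask, pts[i], pts[i + 1], hws[i], hws[i + 1])
        polylines.append(pts)
        halfwidths.append(hws)
        lengths.append(float(np.sum(np.hypot(*np.diff(pts, axis=0).T))))

    # cracks darken all channels; papillae/contour never enter the mask
    image[mask] -= config.contrast_gap

    image = np.clip(np.floor(image + 0.5), 0, 255).astype(np.uint8)
    mask8 = mask.astype(np.uint8)
    label = CRACKED if mask.any() else NON_CRACKED
    meta = {
        "seed": int(seed),
        "polylines": polylines,
        "halfwidths": halfwidths,
        "lengths": lengths,
    }
    return TongueSample(image=image, mask=mask8, label=label, meta=meta)


def generate_dataset(n_pos: int, n_neg: int, config: SynthConfig, seed: int):
    """Generate ``n_pos`` cracked followed by ``n_neg`` non-cracked samples.

    Each sample uses a distinct seed derived from ``seed`` via
    ``numpy.random.SeedSequence``, so the list is deterministic and any
    sample can be regenerated independently.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("sample counts must be non-negative")
    lo, hi = config.n_cracks
    pos_cfg = replace(config, n_cracks=(max(lo, 1), max(hi, 1)))
    neg_cfg = replace(config, n_cracks=(0, 0))
    child_seeds = np.random.SeedSequence(int(seed)).generate_state(n_pos + n_neg)
    samples = []
    for i in range(n_pos):
        sample = render_sample(pos_cfg, int(child_seeds[i]))
        assert sample.label == CRACKED
        samples.append(sample)
    for i in range(n_neg):
        sample = render_sample(neg_cfg, int(child_seeds[n_pos + i]))
        samples.append(sample)
    return samples
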