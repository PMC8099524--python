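"""Synthetic paired image/mask phantoms.

The generator emulates the statistical structure the synthesis method relies
on: a grayscale tissue background, a compact high-contrast "tumor" region,
and a binary mask aligned with it, intensities in [0,1].  Tumors are random
ellipses (optionally with a perturbed boundary); the background is either a
constant level or a smoothed Gaussian random field, since a perfectly
constant background has zero variance and makes structural-similarity
metrics degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as _ellipse


@dataclass
class PairedSample:
    """One 2D intensity image in [0,1] plus its aligned binary ROI mask."""

    image: np.ndarray
    mask: np.ndarray
    sample_id: str
    group_label: str | None = None

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        self.mask = np.asarray(self.mask)
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image shape {self.image.shape} != mask shape {self.mask.shape}")
        if self.image.min() < 0 or self.image.max() > 1:
            raise ValueError("image values must lie in [0,1]")
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be exactly 0 or 1")
        self.mask = self.mask.astype(np.uint8)


@dataclass
class PhantomConfig:
    """Parameters of the phantom generator.

    tumor_radius_range is in pixels; texture_scale is the spatial correlation
    length (pixels) of the background field, 0 disables texture.
    """

    image_size: int = 64
    n_samples: int = 16
    background_level: float = 0.3
    tumor_contrast: float = 0.4
    tumor_radius_range: tuple[int, int] = (6, 14)
    noise_sd: float = 0.0
    texture_scale: float = 0.0
    texture_amplitude: float = 0.05
    boundary_wobble: float = 0.0
    seed: int = 0

    def validate(self):
        if self.image_size < 16:
            raise ValueError("image_size: must be >= 16")
        if self.n_samples < 1:
            raise ValueError("n_samples: must be >= 1")
        if not 0 <= self.background_level <= 1:
            raise ValueError("background_level: must lie in [0,1]")
        if not 0 <= self.tumor_contrast <= 1:
            raise ValueError("tumor_contrast: must lie in [0,1]")
        rmin, rmax = self.tumor_radius_range
        if not (0 < rmin <= rmax < self.image_size / 2):
            raise ValueError(
                "tumor_radius_range: bounds must be positive, ordered and "
                "< image_size/2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd: must be >= 0")
        if self.texture_scale < 0:
            raise ValueError("texture_scale: must be >= 0")


def _ellipse_mask(rng: np.random.Generator, cfg: PhantomConfig) -> np.ndarray:
    s = cfg.image_size
    rmin, rmax = cfg.tumor_radius_range
    a = rng.uniform(rmin, rmax)
    b = rng.uniform(rmin, rmax)
    rot = rng.uniform(0, np.pi)
    margin = int(np.ceil(max(a, b))) + 2
    cy = rng.uniform(margin, s - margin)
    cx = rng.uniform(margin, s - margin)
    mask = np.zeros((s, s), dtype=np.uint8)
    rr, cc = _ellipse(cy, cx, a, b, shape=(s, s), rotation=rot)
    mask[rr, cc] = 1
    if cfg.boundary_wobble > 0:
        # radial sinusoidal perturbation of the boundary
        yy, xx = np.mgrid[0:s, 0:s]
        dy, dx = yy - cy, xx - cx
        theta = np.arctan2(dy, dx)
        phase = rng.uniform(0, 2 * np.pi)
        k = rng.integers(3, 7)
        scale = 1.0 + cfg.boundary_wobble * np.sin(k * theta + phase)
        # re-rasterize: point inside iff the unperturbed radius test passes
        ca, sa = np.cos(rot), np.sin(rot)
        u = (dx * ca + dy * sa) / (b * scale)
        v = (-dx * sa + dy * ca) / (a * scale)
        mask = ((u * u + v * v) <= 1).astype(np.uint8)
    return mask


def generate_phantoms(config: PhantomConfig,
                      group_label: str | None = None) -> list[PairedSample]:
    """Generate ``config.n_samples`` paired phantoms.

    Deterministic: identical config and seed give byte-identical output.
    With noise_sd=0 and texture disabled the image is exactly
    ``background_level + tumor_contrast * mask``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    s = config.image_size
    samples = []
    for i in range(config.n_samples):
        mask = _ellipse_mask(rng, config)
        image = np.full((s, s), config.background_level, dtype=np.float64)
        if config.texture_scale > 0 and config.texture_amplitude > 0:
            tex = gaussian_filter(rng.standard_normal((s, s)),
                                  config.texture_scale)
            sd = tex.std()
            if sd > 0:
                tex *= config.texture_amplitude / sd
            image += tex
        image += config.tumor_contrast * mask
        if config.noise_sd > 0:
            image += rng.normal(0, config.noise_sd, (s, s))
        image = np.clip(image, 0.0, 1.0)
        samples.append(PairedSample(image=image, mask=mask,
                                    sample_id=f"phantom_{i:03d}",
                                    group_label=group_label))
    return samples


def save_phantoms(samples: list[PairedSample], out_dir) -> "object":
    """Export a phantom set as paired 16-bit PNGs plus a CSV manifest.
    Returns the manifest DataFrame. Thin wrapper over the shared pair writer."""
    from .preprocess import write_pairs

    return write_pairs(samples, out_dir)
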