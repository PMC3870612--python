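"""Synthetic radiograph-like phantoms and calibrated Gaussian noise.

The generator emulates the gross structure of mammograms and chest
radiographs at desk scale: a piecewise-smooth low-frequency background,
Gaussian-profile blobs (mass-like objects), thin high-contrast lines
(vessel/rib-like structures) and straight step edges (tissue boundaries).
When ``edges >= 1`` the first edge is always a vertical step at column
``cols // 2``, so profile-based edge tests have a known location.

Noise is additive zero-mean Gaussian with a standard deviation specified on
the [0, 1] normalized intensity scale (the imaging-toolbox convention), so
``sigma = 0.01`` on an 8-bit image is about 2.55 gray levels.  Values are
clipped to the valid range after noise addition.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import InputShapeError, ValidationError
from .image import ImageGrid, as_image

logger = logging.getLogger(__name__)

#: Default additive-noise standard deviation on the [0, 1] scale.
DEFAULT_NOISE_SIGMA = 0.01


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a synthetic test image; identical spec + seed reproduce
    the image bit for bit."""

    rows: int = 256
    cols: int = 256
    bit_depth: int = 8
    background: float = 0.15  # gradient amplitude, [0, 1] scale
    blobs: int = 3
    blob_radius: tuple[float, float] = (8.0, 24.0)
    blob_contrast: tuple[float, float] = (0.1, 0.3)
    lines: int = 2
    line_width: int = 1
    line_contrast: float = 0.15
    edges: int = 1
    edge_contrast: float = 0.2
    seed: int = 0

    @property
    def known_edge_column(self) -> int:
        """Column of the guaranteed vertical step edge (when edges >= 1)."""
        return self.cols // 2


def generate_phantom(spec: PhantomSpec) -> ImageGrid:
    """Render the phantom described by ``spec``."""
    if spec.rows % 4 or spec.cols % 4:
        raise InputShapeError(
            f"phantom dimensions {spec.rows}x{spec.cols} must be divisible by 4"
        )
    rng = np.random.default_rng(spec.seed)
    rr, cc = np.meshgrid(
        np.arange(spec.rows, dtype=float),
        np.arange(spec.cols, dtype=float),
        indexing="ij",
    )

    img = np.full((spec.rows, spec.cols), 0.4)
    if spec.background > 0:
        # smooth gradient: tilted plane plus one low-frequency cosine bump
        theta = rng.uniform(0, 2 * math.pi)
        ramp = (rr / spec.rows) * math.cos(theta) + (cc / spec.cols) * math.sin(theta)
        phase_r, phase_c = rng.uniform(0, 2 * math.pi, size=2)
        wave = np.cos(2 * math.pi * rr / spec.rows + phase_r) * np.cos(
            2 * math.pi * cc / spec.cols + phase_c
        )
        img += spec.background * (0.5 * ramp + 0.25 * wave)

    for k in range(spec.edges):
        if k == 0:
            img[:, spec.known_edge_column :] += spec.edge_contrast
        else:
            if rng.random() < 0.5:
                pos = rng.integers(spec.cols // 4, 3 * spec.cols // 4)
                img[:, pos:] += spec.edge_contrast * rng.choice([-1.0, 1.0])
            else:
                pos = rng.integers(spec.rows // 4, 3 * spec.rows // 4)
                img[pos:, :] += spec.edge_contrast * rng.choice([-1.0, 1.0])

    for _ in range(spec.blobs):
        cy = rng.uniform(0.15 * spec.rows, 0.85 * spec.rows)
        cx = rng.uniform(0.15 * spec.cols, 0.85 * spec.cols)
        radius = rng.uniform(*spec.blob_radius)
        contrast = rng.uniform(*spec.blob_contrast)
        img += contrast * np.exp(-((rr - cy) ** 2 + (cc - cx) ** 2) / (2 * radius**2))

    for _ in range(spec.lines):
        width = max(1, spec.line_width)
        if rng.random() < 0.5:
            pos = int(rng.integers(2, spec.rows - width - 2))
            img[pos : pos + width, :] += spec.line_contrast
        else:
            pos = int(rng.integers(2, spec.cols - width - 2))
            img[:, pos : pos + width] += spec.line_contrast

    max_value = 2**spec.bit_depth - 1
    pixels = np.clip(img, 0.0, 1.0) * max_value
    return ImageGrid(pixels=pixels, bit_depth=spec.bit_depth)


def add_gaussian_noise(
    image: ImageGrid | np.ndarray,
    sigma: float = DEFAULT_NOISE_SIGMA,
    seed: int = 0,
) -> ImageGrid:
    """Add zero-mean Gaussian noise of standard deviation ``sigma``.

    ``sigma`` is on the [0, 1] normalized scale and is rescaled by the
    image's dynamic range; the result is clipped to the valid range.
    """
    if sigma < 0:
        raise ValidationError(f"noise sigma must be >= 0, got {sigma}")
    img = as_image(image)
    if sigma == 0:
        return img.with_pixels(img.pixels.copy())
    rng = np.random.default_rng(seed)
    noisy = img.pixels + rng.normal(0.0, sigma * img.max_value, img.shape)
    clipped = np.clip(noisy, 0.0, img.max_value)
    frac = float((clipped != noisy).mean())
    if frac > 0:
        logger.info("noise clipping affected %.3f%% of pixels", 100 * frac)
    return img.with_pixels(clipped)
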