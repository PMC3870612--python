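"""Grayscale raster container.

All processing stages consume and produce :class:`ImageGrid`: a 2-D float
array of intensities plus a declared bit depth.  Intermediate values may
leave the ``[0, 2**bit_depth - 1]`` range; rounding and clipping happen only
when an image is written to disk.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputShapeError, ValidationError

VALID_BIT_DEPTHS = (8, 12, 16)


@dataclass
class ImageGrid:
    """A single-channel image.

    Parameters
    ----------
    pixels
        2-D array of intensities.  Stored as ``float64``.
    bit_depth
        Declared dynamic range: 8, 12 or 16 bits.  The nominal maximum
        intensity is ``2**bit_depth - 1``.
    """

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise InputShapeError(
                f"expected a 2-D grayscale array, got ndim={self.pixels.ndim}"
            )
        if not np.isfinite(self.pixels).all():
            raise ValidationError("pixel values must all be finite")
        if self.bit_depth not in VALID_BIT_DEPTHS:
            raise ValidationError(
                f"bit_depth must be one of {VALID_BIT_DEPTHS}, got {self.bit_depth}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def max_value(self) -> int:
        """Nominal intensity ceiling, ``2**bit_depth - 1``."""
        return 2**self.bit_depth - 1

    def normalized(self) -> np.ndarray:
        """Pixels rescaled to the [0, 1] intensity scale."""
        return self.pixels / self.max_value

    def clipped(self) -> np.ndarray:
        """Pixels rounded and clipped to the storable integer range."""
        return np.clip(np.rint(self.pixels), 0, self.max_value)

    def with_pixels(self, pixels: np.ndarray) -> "ImageGrid":
        """A new grid with the same bit depth and different pixel data."""
        return ImageGrid(pixels=pixels, bit_depth=self.bit_depth)

    def validate_for_transform(self, levels: int = 2) -> None:
        """Check the shape constraints the wavelet transform requires."""
        rows, cols = self.pixels.shape
        div = 2**levels
        if rows < 8 or cols < 8:
            raise InputShapeError(
                f"transform input must be at least 8x8, got {rows}x{cols}"
            )
        if rows % div or cols % div:
            raise InputShapeError(
                f"dimensions {rows}x{cols} not divisible by 2^levels = {div}"
            )


def as_image(obj, bit_depth: int = 8) -> ImageGrid:
    """Coerce an array or ImageGrid to an ImageGrid."""
    if isinstance(obj, ImageGrid):
        return obj
    return ImageGrid(pixels=np.asarray(obj, dtype=np.float64), bit_depth=bit_depth)
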