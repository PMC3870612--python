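"""Undecimated (stationary) 2-D discrete wavelet transform.

The transform keeps every subband at the source image's size — no
downsampling — which makes it exactly equivariant to circular shifts, the
property that motivates its use over the decimated DWT for denoising.
Deeper levels use the a-trous scheme: the level-1 filters with zeros
inserted between taps.  Boundaries are handled by periodic (circular)
extension, which guarantees exact perfect reconstruction.

The transform engine is PyWavelets (``swt2``/``iswt2``).  Filter phase
convention (fixed, even-phase): the level-j subband at index ``i`` is the
circular convolution sum over taps ``k`` of ``filter[k] *
x[(i - k * 2**(j-1) + 2**j) % n]`` along each axis.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .errors import ConfigurationError, InputShapeError
from .image import ImageGrid, as_image

#: Detail-subband orientations, in the (cH, cV, cD) order PyWavelets uses.
ORIENTATIONS = ("horizontal", "vertical", "diagonal")

DEFAULT_BASIS = "db2"


@dataclass
class WaveletDecomposition:
    """Undecimated wavelet subbands of an image.

    ``approximations[j-1]`` and ``details[j-1]`` hold the level-j
    approximation and the three level-j detail subbands (keys
    ``horizontal``/``vertical``/``diagonal``); every subband has the source
    image's shape.
    """

    levels: int
    basis: str
    approximations: list[np.ndarray]
    details: list[dict[str, np.ndarray]]
    boundary_mode: str = "periodic"
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise InputShapeError("decomposition must have at least one level")
        if len(self.approximations) != self.levels or len(self.details) != self.levels:
            raise InputShapeError(
                "approximation/detail lists must have one entry per level"
            )
        shape = self.approximations[0].shape
        for j in range(self.levels):
            if self.approximations[j].shape != shape:
                raise InputShapeError("inconsistent subband shapes across levels")
            for orient in ORIENTATIONS:
                if orient not in self.details[j]:
                    raise InputShapeError(f"missing {orient} detail at level {j + 1}")
                if self.details[j][orient].shape != shape:
                    raise InputShapeError("inconsistent subband shapes across levels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.approximations[0].shape  # type: ignore[return-value]

    def approximation(self, level: int) -> np.ndarray:
        return self.approximations[level - 1]

    def detail(self, level: int, orientation: str) -> np.ndarray:
        return self.details[level - 1][orientation]

    def copy(self) -> "WaveletDecomposition":
        return WaveletDecomposition(
            levels=self.levels,
            basis=self.basis,
            approximations=[a.copy() for a in self.approximations],
            details=[{k: v.copy() for k, v in d.items()} for d in self.details],
            boundary_mode=self.boundary_mode,
            bit_depth=self.bit_depth,
        )

    def level_subset(self, level: int) -> "WaveletDecomposition":
        """A one-level decomposition holding only the given level's subbands.

        Reconstructing the subset of level 1 yields the image implied by the
        level-1 approximation plus level-1 details alone, which is how the
        denoiser rebuilds its output.
        """
        return WaveletDecomposition(
            levels=1,
            basis=self.basis,
            approximations=[self.approximations[level - 1]],
            details=[self.details[level - 1]],
            boundary_mode=self.boundary_mode,
            bit_depth=self.bit_depth,
        )


def _wavelet(basis: str) -> pywt.Wavelet:
    try:
        wav = pywt.Wavelet(basis)
    except ValueError as exc:
        raise ConfigurationError(f"unsupported wavelet basis {basis!r}") from exc
    return wav


def udwt_decompose(
    image: ImageGrid | np.ndarray, levels: int = 2, basis: str = DEFAULT_BASIS
) -> WaveletDecomposition:
    """Decompose an image into undecimated wavelet subbands.

    Parameters
    ----------
    image
        Input grid (or bare 2-D array); dimensions must be divisible by
        ``2**levels`` and at least 8.
    levels
        Number of decomposition levels, 1 or 2.
    basis
        Wavelet basis name; ``db2`` is the default and the basis the
        denoise/enhance pipeline is calibrated for.
    """
    if levels not in (1, 2):
        raise ConfigurationError(f"levels must be 1 or 2, got {levels}")
    wav = _wavelet(basis)
    img = as_image(image)
    img.validate_for_transform(levels)

    coeffs = pywt.swt2(img.pixels, wav, level=levels)  # coarsest level first
    approximations: list[np.ndarray] = [None] * levels  # type: ignore[list-item]
    details: list[dict[str, np.ndarray]] = [None] * levels  # type: ignore[list-item]
    for idx, (c_a, (c_h, c_v, c_d)) in enumerate(coeffs):
        level = levels - idx
        approximations[level - 1] = c_a
        details[level - 1] = {
            "horizontal": c_h,
            "vertical": c_v,
            "diagonal": c_d,
        }
    return WaveletDecomposition(
        levels=levels,
        basis=basis,
        approximations=approximations,
        details=details,
        bit_depth=img.bit_depth,
    )


def udwt_reconstruct(dec: WaveletDecomposition) -> ImageGrid:
    """Invert :func:`udwt_decompose`.

    Uses the coarsest approximation plus the detail subbands of every level.
    To reconstruct from level-1 subbands only (as the denoiser does), pass
    ``dec.level_subset(1)``.
    """
    wav = _wavelet(dec.basis)
    coeffs = []
    for level in range(dec.levels, 0, -1):  # coarsest first
        d = dec.details[level - 1]
        coeffs.append(
            (
                dec.approximations[level - 1],
                (d["horizontal"], d["vertical"], d["diagonal"]),
            )
        )
    pixels = pywt.iswt2(coeffs, wav)
    return ImageGrid(pixels=pixels, bit_depth=dec.bit_depth)
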