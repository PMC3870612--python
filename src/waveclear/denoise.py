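"""Noise suppression via inter-level hierarchical-correlation thresholding.

True image structure (edges, lines) produces detail coefficients that
persist across scales, so the elementwise product of level-1 and level-2
detail coefficients is large where signal lives and small where noise
dominates.  The denoiser:

1. decomposes the image to level 2 with the undecimated transform;
2. forms, per orientation, the correlation image
   ``|coef_lev1(p, q) * coef_lev2(p, q)|``;
3. derives a threshold per orientation: take the maximum of each row of the
   correlation image, average those row maxima (``mean_max``), discard
   correlation values greater than ``0.8 * mean_max`` (those are signal),
   compute the standard deviation sigma of the remainder, and set
   ``THR = 1.6 * sigma``;
4. zeroes every level-1 detail coefficient whose correlation falls below
   THR, leaving the approximation untouched;
5. reconstructs from the level-1 approximation plus the modified level-1
   details.

The 0.8 and 1.6 constants are empirical; both are exposed as parameters.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import InputShapeError, ValidationError
from .image import ImageGrid, as_image
from .wavelet_core import (
    DEFAULT_BASIS,
    ORIENTATIONS,
    WaveletDecomposition,
    udwt_decompose,
    udwt_reconstruct,
)

logger = logging.getLogger(__name__)

#: Fraction of the mean row-maximum above which correlation values are
#: treated as signal and excluded from the noise-sigma estimate.
DEFAULT_CORR_EXCLUSION = 0.8
#: Multiplier turning the retained values' standard deviation into THR.
DEFAULT_THR_SCALE = 1.6

#: orientation -> correlation image (same shape as the source)
CorrelationMap = dict[str, np.ndarray]


@dataclass(frozen=True)
class Threshold:
    """Per-orientation threshold statistics."""

    mean_max: float
    sigma: float
    thr: float


#: orientation -> Threshold
ThresholdSet = dict[str, Threshold]


def hierarchical_correlation(dec: WaveletDecomposition) -> CorrelationMap:
    """Elementwise ``|level-1 coef * level-2 coef|`` per detail orientation."""
    if dec.levels < 2:
        raise InputShapeError(
            "hierarchical correlation requires a level-2 decomposition"
        )
    return {
        orient: np.abs(dec.detail(1, orient) * dec.detail(2, orient))
        for orient in ORIENTATIONS
    }


def compute_threshold(
    corr: CorrelationMap,
    exclusion: float = DEFAULT_CORR_EXCLUSION,
    scale: float = DEFAULT_THR_SCALE,
) -> ThresholdSet:
    """Empirical per-orientation thresholds from a correlation map.

    For each orientation independently: row-wise maxima (along the
    horizontal axis), their mean ``mean_max``, exclusion of values strictly
    greater than ``exclusion * mean_max``, population standard deviation of
    the remainder, and ``thr = scale * sigma``.
    """
    if not corr:
        raise ValidationError("empty correlation map")
    out: ThresholdSet = {}
    for orient, img in corr.items():
        row_max = img.max(axis=1)
        mean_max = float(row_max.mean())
        retained = img[img <= exclusion * mean_max]
        if retained.size == 0:
            logger.warning(
                "degenerate correlation map (%s): no values retained, THR := 0",
                orient,
            )
            sigma = 0.0
        else:
            sigma = float(retained.std())  # population (n divisor)
        out[orient] = Threshold(mean_max=mean_max, sigma=sigma, thr=scale * sigma)
    return out


def apply_threshold(
    dec: WaveletDecomposition, corr: CorrelationMap, thr: ThresholdSet
) -> WaveletDecomposition:
    """Zero level-1 detail coefficients whose correlation falls below THR.

    Coefficients with ``corr >= thr`` are kept as-is; approximations and
    deeper levels are untouched.
    """
    out = dec.copy()
    for orient in ORIENTATIONS:
        c = corr[orient]
        if c.shape != dec.shape:
            raise InputShapeError(
                f"correlation shape {c.shape} does not match subbands {dec.shape}"
            )
        band = out.details[0][orient]
        band[c < thr[orient].thr] = 0.0
    return out


def denoise_image(
    image: ImageGrid | np.ndarray,
    basis: str = DEFAULT_BASIS,
    corr_exclusion: float = DEFAULT_CORR_EXCLUSION,
    thr_scale: float = DEFAULT_THR_SCALE,
    passes: int = 1,
) -> ImageGrid:
    """Full denoising pass: decompose, correlate, threshold, reconstruct.

    Reconstruction uses only the level-1 approximation and the modified
    level-1 details.  ``passes`` reruns the whole procedure on its own
    output (default one pass).
    """
    if passes < 1:
        raise ValidationError("passes must be >= 1")
    img = as_image(image)
    for _ in range(passes):
        dec = udwt_decompose(img, levels=2, basis=basis)
        corr = hierarchical_correlation(dec)
        thr = compute_threshold(corr, exclusion=corr_exclusion, scale=thr_scale)
        for orient, t in thr.items():
            logger.info(
                "denoise %s: mean_max=%.6g sigma=%.6g THR=%.6g",
                orient,
                t.mean_max,
                t.sigma,
                t.thr,
            )
        masked = apply_threshold(dec, corr, thr)
        img = udwt_reconstruct(masked.level_subset(1))
    return img
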