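"""Contrast enhancement by sigmoid-type wavelet-coefficient mapping.

Detail coefficients at each level are first expressed "in percent": scaled
so the mean absolute coefficient at level j (pooled over the three
orientations) equals 50.  Each percent-scale magnitude then picks a gain
from a level-dependent sigmoid

    g(w) = a_j / (1 + exp(-(w - c_j) / b)),

and the coefficient's magnitude is multiplied by that gain (sign
preserved).  The amplitude follows a_j = 2 - (j - 1)/N for maximum level N,
so finer levels — which carry edge information — are amplified more, up to
the 2x cap at level 1.  The center c_j = d + b * ln(a_j - 1) places the
half-gain point; with the defaults b = 20 and d = 25, c_1 = 25.
Approximation coefficients are never manipulated, which protects the
image's low-frequency content from distortion.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InputShapeError
from .image import ImageGrid, as_image
from .wavelet_core import (
    DEFAULT_BASIS,
    ORIENTATIONS,
    WaveletDecomposition,
    udwt_decompose,
    udwt_reconstruct,
)

logger = logging.getLogger(__name__)

DEFAULT_GRADIENT = 20.0  # b: sigmoid gradient constant
DEFAULT_INFLECTION = 25.0  # d: inflection-point constant

#: Percent-scale target for the pooled mean absolute coefficient per level.
PERCENT_TARGET = 50.0


@dataclass(frozen=True)
class MappingParams:
    """Sigmoid-gain constants per decomposition level.

    ``amplitudes[j-1]`` is a_j, ``centers[j-1]`` is c_j.
    """

    levels: int
    b: float
    d: float
    amplitudes: tuple[float, ...]
    centers: tuple[float, ...]

    def amplitude(self, level: int) -> float:
        return self.amplitudes[level - 1]

    def center(self, level: int) -> float:
        return self.centers[level - 1]


def build_mapping_params(
    levels: int = 2,
    b: float = DEFAULT_GRADIENT,
    d: float = DEFAULT_INFLECTION,
) -> MappingParams:
    """Populate a_j and c_j for levels 1..N.

    a_j = 2 - (j - 1)/N must stay above 1 for ln(a_j - 1) to exist; this
    holds for every j <= N, so any N >= 1 is valid.
    """
    if levels < 1:
        raise ConfigurationError("levels must be >= 1")
    if b <= 0:
        raise ConfigurationError("gradient constant b must be positive")
    amplitudes = []
    centers = []
    for j in range(1, levels + 1):
        a_j = 2.0 - (j - 1) / levels
        if a_j <= 1.0:
            raise ConfigurationError(
                f"amplitude a_{j} = {a_j} <= 1 leaves the sigmoid center undefined"
            )
        amplitudes.append(a_j)
        centers.append(d + b * math.log(a_j - 1.0))
    return MappingParams(
        levels=levels, b=b, d=d, amplitudes=tuple(amplitudes), centers=tuple(centers)
    )


def percent_normalize(
    details: dict[str, np.ndarray],
) -> tuple[dict[str, np.ndarray], float | None]:
    """Scale one level's detail subbands to percent units.

    Returns the scaled subbands and the scale factor
    ``50 / mean(|w| pooled over orientations)``.  An all-zero level cannot
    be scaled; it is returned unchanged with scale ``None`` (pass-through).
    """
    pooled_mean = float(np.mean([np.abs(details[o]).mean() for o in ORIENTATIONS]))
    if pooled_mean == 0.0:
        logger.warning("all-zero detail level: percent scaling passed through")
        return {o: details[o].copy() for o in ORIENTATIONS}, None
    scale = PERCENT_TARGET / pooled_mean
    return {o: details[o] * scale for o in ORIENTATIONS}, scale


def sigmoid_gain(
    w_pct: np.ndarray | float, level: int, params: MappingParams
) -> np.ndarray | float:
    """Gain a_j / (1 + exp(-(w_pct - c_j)/b)); strictly within (0, a_j)."""
    a_j = params.amplitude(level)
    c_j = params.center(level)
    with np.errstate(over="ignore"):  # exp overflow saturates the gain to 0
        return a_j / (1.0 + np.exp(-(np.asarray(w_pct, dtype=float) - c_j) / params.b))


def enhance_decomposition(
    dec: WaveletDecomposition, params: MappingParams
) -> WaveletDecomposition:
    """Apply the sigmoid gain to every detail coefficient.

    Each coefficient w at level j becomes
    ``sign(w) * g(scale_j * |w|) * |w|``; the approximation subbands are
    returned bit-identical.
    """
    if dec.levels != params.levels:
        raise InputShapeError(
            f"decomposition has {dec.levels} levels but params expect {params.levels}"
        )
    out = dec.copy()
    for level in range(1, dec.levels + 1):
        scaled, scale = percent_normalize(dec.details[level - 1])
        if scale is None:
            continue  # pass-through level
        logger.info(
            "enhance level %d: a=%.6g c=%.6g percent scale=%.6g",
            level,
            params.amplitude(level),
            params.center(level),
            scale,
        )
        for orient in ORIENTATIONS:
            w = dec.details[level - 1][orient]
            gain = sigmoid_gain(np.abs(scaled[orient]), level, params)
            out.details[level - 1][orient] = np.sign(w) * gain * np.abs(w)
    return out


def enhance_image(
    image: ImageGrid | np.ndarray,
    params: MappingParams | None = None,
    basis: str = DEFAULT_BASIS,
) -> ImageGrid:
    """Decompose, remap detail coefficients, reconstruct."""
    if params is None:
        params = build_mapping_params()
    img = as_image(image)
    dec = udwt_decompose(img, levels=params.levels, basis=basis)
    enhanced = enhance_decomposition(dec, params)
    return udwt_reconstruct(enhanced)
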