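"""Image-quality metrics and observer-score aggregation.

Four quantitative metrics:

* MSR — mean-to-standard-deviation ratio inside a desired region of
  interest (DROI): ``mu_d / sigma_d``.
* CNR — contrast-to-noise ratio between the DROI and an undesired region
  (UROI): ``|mu_d - mu_u| / sqrt(0.5 * (sigma_d**2 + sigma_u**2))``.
* CIR — contrast improvement ratio between an original and an enhanced
  image: local contrast ``c = |p - a| / |p + a|`` with p the 3x3 and a the
  7x7 window mean around each pixel, then
  ``CIR = sum((c - c')**2) / sum(c**2)`` over pixels with full 7x7 support.
* PSNR — peak signal-to-noise ratio in dB against a reference:
  ``10 log10(M N T^2 / sum((d - d')**2))`` with ``T = 2**bit_depth - 1``.

Standard deviations are population (n divisor) throughout.

Observer preference scores from paired-comparison reading studies (each
method pair graded on a -2..+2 scale by several observers) are aggregated
into per-pair sums and per-method average preference degrees.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

from .errors import DegenerateRegionError, InputShapeError, ValidationError
from .image import ImageGrid, as_image

#: Half-width of the larger CIR window; only pixels at least this far from
#: every border are evaluated, so results are padding-independent.
CIR_MARGIN = 3


@dataclass(frozen=True)
class RegionSpec:
    """Rectangular ROI, 0-based, half-open ``[start, end)`` on both axes."""

    row_start: int
    col_start: int
    row_end: int
    col_end: int
    role: str = "desired"

    def extract(self, image: ImageGrid | np.ndarray) -> np.ndarray:
        pixels = as_image(image).pixels
        rows, cols = pixels.shape
        if not (
            0 <= self.row_start < self.row_end <= rows
            and 0 <= self.col_start < self.col_end <= cols
        ):
            raise ValidationError(
                f"region {self} is empty or outside a {rows}x{cols} image"
            )
        return pixels[self.row_start : self.row_end, self.col_start : self.col_end]


@dataclass(frozen=True)
class QualityReport:
    """MSR/CNR/CIR/PSNR results; PSNR is ``inf`` for identical images."""

    msr: float | None = None
    cnr: float | None = None
    cir: float | None = None
    psnr: float | None = None

    def as_dict(self) -> dict[str, float]:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def msr(image: ImageGrid | np.ndarray, droi: RegionSpec) -> float:
    """Mean-to-standard-deviation ratio within the DROI."""
    region = droi.extract(image)
    sigma = float(region.std())
    if sigma == 0.0:
        raise DegenerateRegionError("constant DROI: standard deviation is zero")
    return float(region.mean()) / sigma


def cnr(
    image: ImageGrid | np.ndarray, droi: RegionSpec, uroi: RegionSpec
) -> float:
    """Contrast-to-noise ratio between the DROI and the UROI."""
    d = droi.extract(image)
    u = uroi.extract(image)
    pooled = 0.5 * (float(d.std()) ** 2 + float(u.std()) ** 2)
    if pooled == 0.0:
        raise DegenerateRegionError("both regions constant: zero pooled variance")
    return abs(float(d.mean()) - float(u.mean())) / math.sqrt(pooled)


def _local_contrast(pixels: np.ndarray) -> np.ndarray:
    """``|p - a| / |p + a|`` per pixel, p = 3x3 mean, a = 7x7 mean.

    Pixels where ``p + a == 0`` get contrast 0.  Only interior values (full
    7x7 support) are meaningful; callers must crop by :data:`CIR_MARGIN`.
    """
    p = uniform_filter(pixels, size=3, mode="constant")
    a = uniform_filter(pixels, size=7, mode="constant")
    denom = np.abs(p + a)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, np.abs(p - a) / denom, 0.0)
    return c


def cir(
    original: ImageGrid | np.ndarray, enhanced: ImageGrid | np.ndarray
) -> float:
    """Contrast improvement ratio of ``enhanced`` relative to ``original``."""
    orig = as_image(original).pixels
    enh = as_image(enhanced).pixels
    if orig.shape != enh.shape:
        raise InputShapeError(
            f"shape mismatch: original {orig.shape} vs enhanced {enh.shape}"
        )
    m = CIR_MARGIN
    if orig.shape[0] <= 2 * m or orig.shape[1] <= 2 * m:
        raise InputShapeError("image too small for a 7x7 local-contrast window")
    c = _local_contrast(orig)[m:-m, m:-m]
    c_enh = _local_contrast(enh)[m:-m, m:-m]
    denom = float((c**2).sum())
    if denom == 0.0:
        raise DegenerateRegionError("original has zero local contrast everywhere")
    return float(((c - c_enh) ** 2).sum()) / denom


def psnr(
    reference: ImageGrid | np.ndarray, processed: ImageGrid | np.ndarray
) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` for identical images."""
    ref = as_image(reference)
    proc = as_image(processed)
    if ref.shape != proc.shape:
        raise InputShapeError(
            f"shape mismatch: reference {ref.shape} vs processed {proc.shape}"
        )
    if ref.bit_depth != proc.bit_depth:
        raise InputShapeError(
            f"bit-depth mismatch: {ref.bit_depth} vs {proc.bit_depth}"
        )
    err = float(((ref.pixels - proc.pixels) ** 2).sum())
    if err == 0.0:
        return math.inf
    rows, cols = ref.shape
    t = float(ref.max_value)
    return 10.0 * math.log10(rows * cols * t**2 / err)


@dataclass
class ScoreTable:
    """Paired-comparison preference scores.

    ``combinations[i]`` is the ordered method pair (left, right) of the i-th
    comparison; ``scores[i]`` holds one mean score per observer on the
    -2..+2 scale (positive favours the left method).
    """

    combinations: list[tuple[str, str]]
    scores: list[list[float]]

    def __post_init__(self) -> None:
        if len(self.combinations) != len(self.scores):
            raise ValidationError("one score row required per combination")
        n_obs = {len(row) for row in self.scores}
        if len(n_obs) > 1:
            raise ValidationError("inconsistent observer count across combinations")
        for row in self.scores:
            for s in row:
                if not -2.0 <= s <= 2.0:
                    raise ValidationError(f"score {s} outside the [-2, +2] scale")

    @property
    def n_observers(self) -> int:
        return len(self.scores[0]) if self.scores else 0


def aggregate_preference_scores(
    table: ScoreTable,
) -> tuple[dict[tuple[str, str], float], dict[str, float]]:
    """Per-combination score sums and per-method average preference degrees.

    The sum for a combination is the total of its per-observer scores.  A
    method's average preference degree is its average main effect: the sum
    of its signed scores over every pairing it appears in (positive when it
    is the left method, negated when it is the right), divided by
    (number of its pairings x number of observers).
    """
    sums: dict[tuple[str, str], float] = {}
    signed: dict[str, float] = {}
    pairings: dict[str, int] = {}
    for pair, row in zip(table.combinations, table.scores):
        total = float(sum(row))
        sums[pair] = total
        left, right = pair
        signed[left] = signed.get(left, 0.0) + total
        signed[right] = signed.get(right, 0.0) - total
        pairings[left] = pairings.get(left, 0) + 1
        pairings[right] = pairings.get(right, 0) + 1
    degrees = {
        method: signed[method] / (pairings[method] * table.n_observers)
        for method in signed
    }
    return sums, degrees
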