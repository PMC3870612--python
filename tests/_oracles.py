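"""Independent brute-force oracles, deliberately written as straight-line
code with explicit loops, separate from every library path they check."""
from __future__ import annotations

import math

import numpy as np

# Orthonormal db2 analysis filters, closed form.
_SQRT3 = math.sqrt(3.0)
_DENOM = 4.0 * math.sqrt(2.0)
DB2_LO = np.array(
    [(1 - _SQRT3) / _DENOM, (3 - _SQRT3) / _DENOM,
     (3 + _SQRT3) / _DENOM, (1 + _SQRT3) / _DENOM]
)
# quadrature mirror: g[k] = (-1)^(k+1) h[L-1-k]
DB2_HI = np.array(
    [(-1) ** (k + 1) * DB2_LO[len(DB2_LO) - 1 - k] for k in range(len(DB2_LO))]
)


def circular_conv_1d(signal: np.ndarray, filt: np.ndarray, dilation: int) -> np.ndarray:
    """Periodic convolution with an a-trous-dilated filter.

    Even-phase convention: out[i] = sum_k filt[k] * x[(i - k*dilation + 2*dilation) % n].
    """
    n = len(signal)
    offset = 2 * dilation
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for k, f in enumerate(filt):
            acc += f * signal[(i - k * dilation + offset) % n]
        out[i] = acc
    return out


def udwt_level(
    arr: np.ndarray, dilation: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One undecimated level by explicit separable periodic convolution.

    Returns (approx, horizontal, vertical, diagonal).  The horizontal
    detail is high-pass along rows (axis 0) and low-pass along columns
    (it responds to horizontal structure), matching the transform engine's
    (cH, cV, cD) convention.
    """
    rows, cols = arr.shape
    lo_c = np.zeros_like(arr)
    hi_c = np.zeros_like(arr)
    for r in range(rows):
        lo_c[r] = circular_conv_1d(arr[r], DB2_LO, dilation)
        hi_c[r] = circular_conv_1d(arr[r], DB2_HI, dilation)
    approx = np.zeros_like(arr)
    horiz = np.zeros_like(arr)
    vert = np.zeros_like(arr)
    diag = np.zeros_like(arr)
    for c in range(cols):
        approx[:, c] = circular_conv_1d(lo_c[:, c], DB2_LO, dilation)
        vert[:, c] = circular_conv_1d(hi_c[:, c], DB2_LO, dilation)
        horiz[:, c] = circular_conv_1d(lo_c[:, c], DB2_HI, dilation)
        diag[:, c] = circular_conv_1d(hi_c[:, c], DB2_HI, dilation)
    return approx, horiz, vert, diag


def udwt_two_levels(arr: np.ndarray):
    """Levels 1 and 2 of the undecimated transform, brute force."""
    level1 = udwt_level(arr, dilation=1)
    level2 = udwt_level(level1[0], dilation=2)
    return level1, level2


def denoise_chain(
    details1: dict, details2: dict, exclusion: float = 0.8, scale: float = 1.6
):
    """Straight-line correlation -> threshold -> mask chain.

    Returns (correlations, thresholds, masked level-1 details), all computed
    with explicit loops.
    """
    corrs = {}
    thrs = {}
    masked = {}
    for orient in ("horizontal", "vertical", "diagonal"):
        d1 = details1[orient]
        d2 = details2[orient]
        rows, cols = d1.shape
        corr = np.zeros((rows, cols))
        for i in range(rows):
            for j in range(cols):
                corr[i, j] = abs(d1[i, j] * d2[i, j])
        row_maxima = [max(corr[i, j] for j in range(cols)) for i in range(rows)]
        mean_max = sum(row_maxima) / rows
        retained = [
            corr[i, j]
            for i in range(rows)
            for j in range(cols)
            if corr[i, j] <= exclusion * mean_max
        ]
        if retained:
            mean_r = sum(retained) / len(retained)
            sigma = math.sqrt(sum((v - mean_r) ** 2 for v in retained) / len(retained))
        else:
            sigma = 0.0
        thr = scale * sigma
        out = np.zeros((rows, cols))
        for i in range(rows):
            for j in range(cols):
                out[i, j] = d1[i, j] if corr[i, j] >= thr else 0.0
        corrs[orient] = corr
        thrs[orient] = thr
        masked[orient] = out
    return corrs, thrs, masked


def msr_oracle(region: np.ndarray) -> float:
    vals = [float(v) for v in region.ravel()]
    mu = sum(vals) / len(vals)
    var = sum((v - mu) ** 2 for v in vals) / len(vals)
    return mu / math.sqrt(var)


def cnr_oracle(d_region: np.ndarray, u_region: np.ndarray) -> float:
    def stats(reg):
        vals = [float(v) for v in reg.ravel()]
        mu = sum(vals) / len(vals)
        var = sum((v - mu) ** 2 for v in vals) / len(vals)
        return mu, var

    mu_d, var_d = stats(d_region)
    mu_u, var_u = stats(u_region)
    return abs(mu_d - mu_u) / math.sqrt(0.5 * (var_d + var_u))


def _window_mean(img: np.ndarray, i: int, j: int, half: int) -> float:
    vals = [
        img[r, c]
        for r in range(i - half, i + half + 1)
        for c in range(j - half, j + half + 1)
    ]
    return sum(vals) / len(vals)


def local_contrast_oracle(img: np.ndarray, i: int, j: int) -> float:
    p = _window_mean(img, i, j, 1)
    a = _window_mean(img, i, j, 3)
    if p + a == 0:
        return 0.0
    return abs(p - a) / abs(p + a)


def cir_oracle(original: np.ndarray, enhanced: np.ndarray) -> float:
    rows, cols = original.shape
    num = 0.0
    den = 0.0
    for i in range(3, rows - 3):
        for j in range(3, cols - 3):
            c = local_contrast_oracle(original, i, j)
            c_e = local_contrast_oracle(enhanced, i, j)
            num += (c - c_e) ** 2
            den += c**2
    return num / den


def psnr_oracle(ref: np.ndarray, proc: np.ndarray, bit_depth: int) -> float:
    rows, cols = ref.shape
    t = 2**bit_depth - 1
    err = 0.0
    for i in range(rows):
        for j in range(cols):
            err += (ref[i, j] - proc[i, j]) ** 2
    return 10.0 * math.log10(rows * cols * t**2 / err)
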