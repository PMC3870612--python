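# Methods

## The transform

Both processing phases run on an undecimated (stationary, "a-trous") 2-D
discrete wavelet transform with the Daubechies-2 basis. No subband is
downsampled, so every coefficient array has the source image's shape and
the transform commutes exactly with circular shifts. Level 2 uses the
level-1 filters with zeros inserted between taps. Boundaries are extended
periodically — the one convention that makes both perfect reconstruction
and shift equivariance exact and therefore testable; the filter phase is
fixed to the even convention (the level-j subband at index *i* is
`sum_k filt[k] * x[(i - k 2^(j-1) + 2^j) mod n]` along each axis). The
engine is PyWavelets' `swt2`/`iswt2`; the test suite checks it coefficient
by coefficient against an explicit periodic-convolution implementation
written from the closed-form db2 taps.

Input dimensions must be divisible by `2^levels` (the phantom generator
always produces compliant sizes). All internal arithmetic is floating
point regardless of declared bit depth; rounding and clipping to
`[0, 2^bit_depth - 1]` happen only at image write-out.

## Denoising

Detail coefficients of genuine structure persist from level 1 to level 2;
independent noise does not. Per orientation (horizontal/vertical/diagonal)
the denoiser forms the correlation image `|coef_lev1 * coef_lev2|`, then:

* row-wise maxima of the correlation image, averaged → `mean_max`;
* values strictly greater than `0.8 * mean_max` are treated as signal and
  excluded;
* `sigma` = **population** standard deviation (n divisor) of the retained
  values, taken about their mean — deterministic, and with ~10^6 values the
  sample/population distinction is negligible;
* `THR = 1.6 * sigma`.

Level-1 detail coefficients with correlation `>= THR` are kept, the rest
zeroed; coefficients are compared raw, with no energy renormalization
between levels. The output is reconstructed from the *level-1*
approximation plus the modified level-1 details — a single decomposition
pass. (The alternative reading, running the whole denoiser twice, is
available via the `passes` parameter / `--passes` flag but is not the
default.) If the retained set is empty the threshold degrades gracefully
to 0 with a warning, which makes the denoiser the identity.

The 0.8 exclusion fraction and the 1.6 scale are empirical calibration
constants of the method; both are exposed (`--corr-exclusion`,
`--thr-scale`) for experimentation.

**A non-obvious behaviour worth knowing:** the *count* of zeroed
coefficients is not monotone in the input noise level on structured
scenes. `mean_max` is pinned by the rows containing strong edges, so as
noise grows the noise correlations rise toward a roughly fixed exclusion
boundary and relatively *more* of them survive the threshold. What is
monotone — and what the test suite asserts — is THR itself, which tracks
the noise level as intended.

## Enhancement

Per level j, the three detail orientations are pooled and rescaled so the
mean absolute coefficient equals 50 ("percent" units); this makes the
sigmoid constants independent of image dynamic range. Each coefficient's
magnitude is then multiplied by

    g(w_pct) = a_j / (1 + exp(-(w_pct - c_j) / b)),

with the sign restored afterward, so positive and negative edge responses
are treated symmetrically. The constants:

| constant | meaning | default |
| --- | --- | --- |
| `N` | maximum decomposition level | 2 |
| `a_j = 2 - (j-1)/N` | gain ceiling at level j; finer levels amplified more, capped at 2x | a_1 = 2, a_2 = 1.5 |
| `b` | sigmoid gradient (percent units) | 20 |
| `d` | inflection-point constant | 25 |
| `c_j = d + b ln(a_j - 1)` | sigmoid center at level j | c_1 = 25, c_2 ≈ 11.14 |

The amplitude rule is deliberately `2 - (j-1)/N` (a ratio, not a product):
it is the only form that keeps `a_j > 1` so that `ln(a_j - 1)` exists, and
it realizes the design intent that finer levels get steeper gain. The gain
is strictly increasing and confined to `(0, a_j)`, so no coefficient's
magnitude is ever amplified beyond `a_j`-fold or driven through zero, and
signs are preserved. Approximation coefficients are never modified, which
protects low-frequency content from distortion. An all-zero detail level
(e.g. a constant image) cannot be percent-scaled and passes through
untouched, with a warning.

The full pipeline re-decomposes the denoised image for the enhancement
phase rather than reusing the denoiser's subbands, and phase 2 uses the
same undecimated transform as phase 1, keeping the composed pipeline
shift-equivariant end to end.

## Quality metrics

* **MSR** = `mu_d / sigma_d` over a desired ROI (DROI); errors on a
  constant region.
* **CNR** = `|mu_d - mu_u| / sqrt(0.5 (sigma_d^2 + sigma_u^2))` between the
  DROI and an undesired ROI. Offset-invariant; MSR instead is invariant to
  positive rescaling.
* **CIR** = `sum (c - c')^2 / sum c^2` where the local contrast
  `c = |p - a| / |p + a|` uses the 3x3 mean `p` and the full 7x7 mean `a`
  (center included) around each pixel. Only pixels with complete 7x7
  support (margin 3) are evaluated, so the value is independent of any
  padding rule; pixels where `p + a = 0` contribute 0 to both sums.
* **PSNR** = `10 log10(M N T^2 / sum (d - d')^2)` with
  `T = 2^bit_depth - 1`; identical images return `inf`.

All standard deviations are population (n divisor). ROIs are caller
supplied: there is no principled automatic placement, and reported MSR/CNR
values are only comparable for identical ROIs.

Observer paired-comparison tables (scores on the -2..+2 scale, positive
favouring the left method of each pair) are aggregated into per-pair sums
and per-method average preference degrees — a method's signed score total
over all its pairings divided by (its pairing count x observer count).
These main effects sum to zero across methods by construction. The variance
decomposition and significance machinery of a full Scheffe analysis are out
of scope.

## The phantom generator

Synthetic scenes stand in for clinical images: a smooth background
(tilted plane + one low-frequency cosine), Gaussian-profile blobs
(mass-like), thin lines (vessel/rib-like), and straight step edges; when
`edges >= 1` the first is always a vertical step at column `cols // 2` so
edge-profile assertions have a known location. Defaults are 256x256 8-bit
with modest contrasts (0.1–0.3 of full range), and test noise is additive
zero-mean Gaussian with sigma = 0.01 on the [0, 1] scale (~2.55 gray
levels at 8 bits), clipped to the valid range afterward; the clipped
fraction is logged. Images are generated with numpy's seeded PCG64
generator, so a spec + seed is bit-reproducible across platforms.

What the phantoms do *not* emulate: anatomical texture, scatter,
detector-specific noise correlations, or the intensity statistics of real
mammograms. Passing tests demonstrate the algorithm's algebraic
correctness and its behaviour on piecewise-smooth scenes with additive
Gaussian noise — not clinical image quality, which requires reader studies
on real data.

## Problem sizes and numerics

The test suite and the acceptance script run at 16x16–256x256: large
enough that the threshold statistics are stable (a 256x256 image gives
~65k correlation values per orientation) while keeping the whole suite in
seconds. Round-trip reconstruction is asserted below 1e-8 maximum absolute
error (measured ~1e-13 at 8-bit scale), shift equivariance below 1e-9
(measured ~1e-14), and the denoising chain is compared against a
straight-line loop implementation for exact equality. Degenerate inputs
are handled explicitly rather than by exception where a sensible identity
exists: empty retained sets (THR = 0), all-zero detail levels
(pass-through), zero images (zero out).
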