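# waveclear

Denoising and contrast enhancement for single-channel medical images
(mammograms, chest radiographs and similar grayscale data), built on the
undecimated (stationary) discrete wavelet transform.

Radiographic images suffer from two coupled problems: quantum noise that
masks subtle structure, and low local contrast at the tissue boundaries a
reader actually cares about. `waveclear` addresses both in sequence:

1. **Denoising by inter-level hierarchical correlation.** The image is
   decomposed to level 2 with an undecimated db2 transform (no
   downsampling, so every subband keeps the image's size and the whole
   chain is shift-invariant). True structure persists across scales, so the
   correlation image

       Img_Cor(p, q) = |Coef_lev1(p, q) x Coef_lev2(p, q)|

   is large at edges and small where noise dominates. A data-driven
   threshold is derived per detail orientation: take the maximum of each
   row of the correlation image, average them (`Mean_max`), discard values
   above `0.8 x Mean_max` (those are signal), and set `THR = 1.6 x sigma`
   of what remains. Level-1 detail coefficients whose correlation falls
   below THR are zeroed; the approximation subband is never touched. The
   denoised image is rebuilt from the level-1 approximation plus the
   modified level-1 details.

2. **Contrast enhancement by sigmoid coefficient mapping.** Detail
   coefficients are rescaled so their mean absolute value per level is 50
   ("percent" units), then each magnitude is multiplied by the
   level-dependent gain

       g(w) = a_j / (1 + exp(-(w - c_j) / b)),   a_j = 2 - (j-1)/N,
       c_j = d + b ln(a_j - 1),

   with defaults `b = 20`, `d = 25`. Strong coefficients (edges) are
   amplified up to `a_j`-fold — at most 2x at the finest level — while weak
   (noisy) ones are attenuated. Approximation coefficients pass through
   unchanged.

The package also provides the four standard quality metrics (MSR, CNR, CIR,
PSNR), aggregation of paired-comparison observer scores, and a synthetic
phantom generator so everything is testable without clinical data.

## Worked example

```sh
# a 256x256 synthetic phantom and a noisy copy (Gaussian, sigma 0.01 on [0,1])
waveclear --quiet phantom clean.png --rows 256 --cols 256 --seed 42
waveclear --quiet phantom noisy.png --rows 256 --cols 256 --seed 42 --noise 0.01

# denoise + enhance, scoring the output against the clean reference
waveclear pipeline noisy.png processed.png --reference clean.png \
    --droi 96,96,160,160 --uroi 8,8,56,56
```

The pipeline logs its fitted statistics to stderr — per orientation the
correlation `mean_max`, the noise `sigma` and `THR = 1.6 sigma`, then the
per-level sigmoid constants:

```
INFO waveclear.denoise: denoise horizontal: mean_max=67.0047 sigma=6.14939 THR=9.83903
INFO waveclear.denoise: denoise vertical: mean_max=1253.14 sigma=50.7092 THR=81.1347
INFO waveclear.denoise: denoise diagonal: mean_max=33.1628 sigma=4.5761 THR=7.32177
INFO waveclear.enhance: enhance level 1: a=2 c=25 percent scale=41.7394
INFO waveclear.enhance: enhance level 2: a=1.5 c=11.1371 percent scale=20.9597
```

and prints the quality report on stdout:

```
msr     4.91466
cnr     1.32292
cir     0.428743
psnr    36.5717
```

MSR (mean/std inside the desired ROI) and CNR (contrast between the desired
and undesired ROI in pooled-noise units) describe the output on its own;
CIR measures how much local contrast changed relative to the reference
(0.43 — substantial enhancement, versus 0.12 for the raw noisy input), and
PSNR is the fidelity to the reference in dB.

The same operations are available as a library:

```python
from waveclear import PhantomSpec, generate_phantom, add_gaussian_noise, \
    denoise_image, enhance_image, psnr

clean = generate_phantom(PhantomSpec(rows=256, cols=256, seed=42))
noisy = add_gaussian_noise(clean, sigma=0.01, seed=1)
restored = enhance_image(denoise_image(noisy))
print(psnr(clean, noisy), psnr(clean, denoise_image(noisy)))
```

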