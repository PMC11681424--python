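# Methods

This note documents the models, parameter choices and known limitations of
`papunmix`. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute.

## Absorbance model and unmixing

A transmitted-light specimen is modeled by Lambert–Beer's law per band:
`g_k = g0_k · 10^(−a_k)` with `a_k = Σ_i c_i ε_i(λ_k)`, where `g0_k` is the
glass (white) intensity, `c_i` the amount of dye i and `ε_i` its spectral
absorption coefficient sampled at the band center. Band sensitivities are
treated as delta functions at the center wavelength; the systematic error
of that approximation on a real filter-based instrument is not modeled.
The default band grid has 14 centers from 440 to 700 nm in 20-nm steps
(the bands tile 440–720 nm).

Amounts are the unconstrained per-pixel least-squares solution
`c = H⁺ a`. Design choices:

- **Log base 10** throughout, fixed by the `10^(−a)` attenuation form.
- **Intensity floor** (default 1 count) before the log: a zero or
  saturated-dark pixel of an integer ADC carries at least quantization
  uncertainty of one count, and the floor keeps absorbance finite. The
  floor caps, and therefore biases low, the absorbance of very dense
  stain; with 12-bit data the cap is `log10(4095) ≈ 3.6`.
- **Negative absorbance is kept.** Shot noise on nearly clear glass can
  push `g > g0`; clipping at zero would bias the background upward, while
  the least-squares solve averages symmetric noise out.
- **Negative amounts** are solved first and then clipped to zero by
  default (`clip_negative=True`), because all downstream masking and
  patch logic assumes nonnegative amounts. Clipping is per-entry and does
  not re-solve, so the other dyes are untouched. Property tests that
  check linearity or exact recovery disable clipping.
- **Rank guard:** a stain matrix with 2-norm condition number above 1e8
  (1e6 at calibration time, configurable) is rejected, naming the most
  collinear dye pair.

The white reference is supplied explicitly (typically the per-band mean
over a user-chosen glass region); there is no auto-detection.

## Stain-matrix calibration

A single-stain pixel has absorbance `a = β ε_l` with unknown abundance β.
The estimator normalizes each pixel's absorbance to unit Euclidean norm,
averages the unit vectors and renormalizes. Normalizing by the norm
(rather than the squared norm) makes the estimator exactly invariant to
per-pixel abundance, which is the property the calibration needs; the
resulting columns are unit vectors, matching the unit-scale normalized
absorbance curves the signatures are compared against. Fewer than 25
calibration pixels (one 5×5 sample) triggers a warning. All-zero pixels
are skipped; an estimate with entries below −0.01 (beyond noise level on
a unit vector) is flagged as a probable contamination of the single-stain
sample.

## Normalization and background elimination

Raw amounts are relative (the column scale is arbitrary), so each dye
plane is divided by a reference value `q_l`: the 99th percentile of that
dye's amounts over manually selected well-stained regions. A bundled
preset (`presets/reference_values.json`: EY 2.003, H 1.889, LG 2.550,
OG 1.213) carries the fixed reference values measured for the 14-band
clinical protocol; for phantoms, references can be recomputed from the
ground-truth masks.

Background thresholds `t_l` are the 99th percentile (configurable) of each
dye's amounts over a user-selected empty-glass region — real slides retain
faint residual stain after washing, so the thresholds are not zero. A
pixel is background iff **every** dye is strictly below its threshold.
Thresholds are applied on whatever scale (raw or normalized) they were
derived on; masking commutes with normalization when thresholds are
scaled alongside, which is verified by a property test. Note that with a
per-dye 99th percentile the *union* over four dyes retains up to ~4% of
true background pixels, not 1%.

## Patch logic

Maps are tiled into non-overlapping `patch_size × patch_size` tiles
(default 10, matching ~2.5 µm at 0.25 µm/pixel) anchored at the image
origin; right/bottom remainders are discarded. Rules, in order:

1. **nucleus** if strictly more than 50% of pixels have H at or above the
   H background threshold (51 of 100 for the default size; exactly half
   does not qualify);
2. **background** if strictly more than `b_percent` (default 90) of
   pixels are non-stained;
3. **mucin** otherwise.

`b_percent` is a dataset-dependent tuning knob and is exposed everywhere.
Patch features are mean amounts over the *stained* pixels only; a patch
with no stained pixel yields an empty marker rather than zeros.
"H-stained" reuses the background threshold `t_H` as the stain criterion —
no separate nuclear cut-off is defined.

## Discriminants and the preset sign convention

`fit_fisher` solves `w = S_W^{-1}(μ_LEGH − μ_EC)` with the pooled
within-class scatter, bias at the equal-prior midpoint
`−w·(μ_EC+μ_LEGH)/2`, and classifies D ≥ 0 (ties included) as the positive
class — LEGH for freshly fitted models. A singular scatter falls back to a
ridge-regularized solve with a warning. The sklearn wrapper
(`FisherDiscriminant`) exposes fit/predict/decision_function and composes
with model selection; its direction agrees with sklearn's LDA on
well-posed problems (cross-checked in tests, not delegated).

The three preset models (2-D EY/OG, 3-D EY/LG/OG, sRGB) ship their
published coefficients verbatim, e.g.
`D_2D = 15.01·EY − 43.55·OG + 1.454`. Evaluating these functions on any
OG-rich (LEGH-like) composition gives D < 0 and on any EY-rich (EC-like)
composition D > 0, and the held-out confusion matrices they were validated
against show near-perfect separation — so the positive side of the printed
functions is EC, even though the accompanying rule was stated as
"D ≥ 0 → LEGH". The presets therefore declare `positive_label="EC"`;
with any other orientation the pipeline would systematically swap EC and
LEGH on real-like data. `positive_label` is explicit on every model, and
evaluation requires the positive class as an argument rather than
hard-coding one (the published precision/recall values are only mutually
consistent under mixed conventions; accuracy and F are convention-checked
in the acceptance suite).

The cluster-level score is the LEGH ratio: LEGH-classified mucin patches
over all mucin patches, with nucleus and background patches excluded;
zero mucin patches yields an undefined marker, not 0.

## sRGB rendering

For visual QC only: band transmittances are linearly interpolated
(edge-extended) to a 5-nm grid on 380–780 nm, weighted by the CIE 1931
2° color-matching functions (the standard piecewise-Gaussian analytic
fit, ~1% accurate) and a daylight illuminant approximated by a 6504 K
Planckian spectrum, converted to linear sRGB, white-balanced per channel
so that full transmittance renders exact white, and gamma-encoded. The
per-channel white balance makes the render invariant to exposure and
nearly invariant to the illuminant approximation, which is why an
analytic illuminant suffices. sRGB discriminant features are means of the
gamma-encoded channels in [0, 1] (the ~±100-scale preset coefficients
against a ±74 bias only produce a usable decision boundary for inputs of
order one, which supports this reading). Colorimetric accuracy is
explicitly out of scope.

## Synthetic phantoms

The generator emulates: cell-like geometry (nucleus ellipse over
cytoplasm ellipse over glass), faint residual background stain
(defaults 0.006–0.012 per dye), Poisson shot noise at a configurable
expected photon count per band on glass (default 10⁴), and ADC
quantization (default 12-bit). Dye spectra are Gaussian-lobe curves with
the qualitative shapes of the real stains (H broad peak 550–600 nm, EY
sharp peak 500–550 nm, LG red+blue absorption with a 480–540 nm window,
OG a 480 nm peak transparent beyond 530 nm); they are *not* measured
spectra. An `overlap_additive` mode adds cytoplasm amounts where cells
overlap, reflecting absorbance additivity of stacked cells. Seeds are
mandatory and all noise flows from one `numpy` generator, so outputs are
bit-reproducible.

The two-class feature sampler draws per-patch mean amounts from isotropic
Gaussians clipped at zero, with class means on the normalized-amount
scale: EC (H 0.01, EY 0.45, LG 0.12, OG 0.01) — pink, EY-rich, OG-free;
LEGH (H 0.01, EY 0.18, LG 0.20, OG 0.35) — yellow, OG-rich, EY-reduced;
spread 0.08. These encode the documented qualitative contrast (LEGH mucin
= more OG, less EY; H absent from mucin) at a separation a Fisher model
should resolve; they are fixed study conditions, not fitting knobs.

What passing on phantoms does **not** show: robustness to real staining
variability, co-staining of nuclei by cytoplasmic dyes, specimen
thickness/defocus effects, instrument spectral-sensitivity error, or
realistic cell morphology and texture. Problem sizes in the tests and the
acceptance script (scenes of ~100–150 px square, 100–200 samples per
class, 20 random unmixing instances) are chosen as the smallest sizes at
which the statistical checks are stable.

## Known limitations

- Single focal plane only; no z-stack or extended-focus handling.
- No blind (calibration-free) stain-matrix estimation.
- Bismarck brown is excluded from the active dye set.
- The narrowband (delta-sensitivity) approximation is accepted as-is.
- Reference values and thresholds assume manual region selection; there
  is no automatic detection of well-stained areas.
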