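# papunmix

Multispectral dye-amount quantification for Papanicolaou-stained cytology,
with patch-wise classification of cytoplasmic mucin as normal endocervical
(EC) or LEGH-type (lobular endocervical glandular hyperplasia, a benign
cervical lesion whose mucin stains yellow/orange instead of pink).

The Papanicolaou stain mixes five dyes, so its color cannot be unmixed
from a 3-channel RGB image; with a multi-band microscope stack (N ≥ 5
bands) the problem becomes overdetermined and per-pixel dye amounts can be
estimated from a physical absorbance model. `papunmix` implements that
pipeline end to end for the four diagnostically informative dyes —
hematoxylin (H), eosin Y (EY), light green SF (LG) and orange G (OG) — and
is aimed at digital-pathology researchers who want quantitative,
device-independent color features from cytology slides.

## Model

For band k with glass (incident) intensity `g0_k` and observed intensity
`g_k`, Lambert–Beer's law with narrowband sensitivities gives the
absorbance and its linear mixing model

```
a_k = log10(g0_k / g_k),        a = H c,
```

where the stain matrix `H ∈ R^{N×M}` holds one unit-norm spectral
absorption column per dye and `c ≥ 0` are the per-pixel dye amounts. With
M < N the amounts are recovered by the Moore–Penrose pseudo-inverse,
`c = H⁺ a`. `H` is calibrated from single-stain specimens (each pixel's
absorbance is proportional to the dye column), amounts are normalized by
per-dye reference values so "well stained" ≈ 1, background glass is masked
by per-dye thresholds taken from a user-selected empty region, and 10×10
patches are labeled nucleus / background / mucin. Mucin patches are
classified EC vs. LEGH by Fisher linear discriminants over mean dye
amounts; fixed published coefficients for 2-D (EY, OG), 3-D (EY, LG, OG)
and an sRGB baseline ship as presets, and new discriminants can be fitted
with `fit_fisher` or the scikit-learn-style `FisherDiscriminant`.

Because clinical specimens are not distributable, the `synthetic` module
renders phantom scenes (cell-like ellipses, shot noise, ADC quantization)
with known ground truth; all tests run on those.

## Worked example

```python
import numpy as np
from papunmix import (
    Cell, PhantomScene, analyze_patches, cluster_legh_ratio, compute_absorbance,
    default_spectra, default_white, derive_background_thresholds, preset_models,
    render_phantom, unmix,
)

stains = default_spectra()                      # 14-band phantom stain matrix
white = default_white(stains.wavelengths_nm)    # flat 12-bit white reference

cell = Cell(center=(40, 40), cytoplasm_axes=(26, 30), nucleus_axes=(8, 7),
            cytoplasm_amounts={"EY": 0.15, "LG": 0.08, "OG": 0.40},
            nucleus_amounts={"H": 0.9, "EY": 0.05})
scene = PhantomScene(shape=(96, 96), cells=[cell], seed=42)
stack, truth, labels = render_phantom(scene, stains, white)

amounts = unmix(compute_absorbance(stack, white), stains)
thresholds = derive_background_thresholds(amounts, labels == 0)
patches = analyze_patches(amounts, thresholds, model=preset_models()["fisher_3d"])

mucin = [p for p in patches if p.label == "mucin"]
print(f"condition number: {stains.condition_number():.2f}")
print(f"patches: {len(patches)}  mucin: {len(mucin)}  "
      f"nucleus: {sum(p.label == 'nucleus' for p in patches)}  "
      f"background: {sum(p.label == 'background' for p in patches)}")
mean = np.mean([p.mean_amounts for p in mucin], axis=0)
print("mean mucin amounts:",
      ", ".join(f"{d}={v:.3f}" for d, v in zip(stains.dye_names, mean)))
print(f"LEGH ratio: {cluster_legh_ratio(patches):.3f}")
```

prints

```
condition number: 2.96
patches: 81  mucin: 31  nucleus: 1  background: 49
mean mucin amounts: H=0.039, EY=0.142, LG=0.075, OG=0.371
LEGH ratio: 1.000
```

The stain matrix is well conditioned (2.96), the single simulated cell
yields one nucleus patch and 31 mucin patches, the unmixed mucin amounts
recover the scene's OG-rich cytoplasm (OG ≈ 0.37 against a ground truth of
0.40, with shot noise and the residual glass stain accounting for the
difference), and every mucin patch of this OG-rich cell is classified
LEGH — the cluster-level LEGH ratio is 1.0.

The same workflow is available from the shell via the `papunmix` CLI
(`simulate`, `calibrate`, `unmix`, `render`, `region-report`, `classify`,
`evaluate`); every command writes a provenance JSON so identical
invocations give identical outputs.

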