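"""Synthetic multispectral phantoms with known ground truth.

Clinical Papanicolaou slides are not distributable, so every stage of the
pipeline is exercised on phantoms: cell-like scenes (nucleus and cytoplasm
ellipses on faintly stained glass) are composited into a ground-truth
dye-amount map, pushed through the Lambert-Beer forward model, degraded
with Poisson shot noise at a configurable photon budget, and quantized to
a configurable ADC bit depth.  Generation is fully deterministic under the
scene's mandatory seed.

The four default dye spectra follow the qualitative absorption shapes of
the real stains on the 14-band grid: hematoxylin a broad peak between 550
and 600 nm, eosin Y a sharp peak between 500 and 550 nm, light green SF
absorbing in the blue and red but hardly between 480 and 540 nm, and
orange G absorbing near 480 nm and essentially transparent beyond 530 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .spectral import compute_absorbance, forward_model
from .types import (
    DEFAULT_DYES,
    DEFAULT_WAVELENGTHS_NM,
    DyeAmountMap,
    MSImage,
    StainMatrix,
    WhiteReference,
)

__all__ = [
    "default_spectra",
    "default_white",
    "Cell",
    "PhantomScene",
    "render_phantom",
    "single_stain_absorbances",
    "TwoClassEffect",
    "make_two_class_dataset",
]

#: Gaussian lobes (center nm, sigma nm, relative height) per dye.
_DYE_LOBES: dict[str, list[tuple[float, float, float]]] = {
    "H": [(575.0, 45.0, 1.0)],
    "EY": [(525.0, 18.0, 1.0)],
    "LG": [(635.0, 40.0, 1.0), (445.0, 25.0, 0.35)],
    "OG": [(482.0, 27.0, 1.0)],
}

#: Label-map codes of rendered phantoms.
LABEL_GLASS, LABEL_CYTOPLASM, LABEL_NUCLEUS = 0, 1, 2


def default_spectra(wavelengths_nm=None) -> StainMatrix:
    """Unit-norm phantom absorption spectra of H, EY, LG and OG."""
    wl = (
        DEFAULT_WAVELENGTHS_NM.copy()
        if wavelengths_nm is None
        else np.asarray(wavelengths_nm, dtype=float)
    )
    if wl.size < 5 or wl[0] > 500 or wl[-1] < 600:
        raise ValidationError(
            "need at least 5 bands spanning the 440-720 nm range for "
            "non-collinear dye spectra"
        )
    cols = []
    for dye in DEFAULT_DYES:
        col = np.zeros_like(wl)
        for mu, sigma, height in _DYE_LOBES[dye]:
            col += height * np.exp(-0.5 * ((wl - mu) / sigma) ** 2)
        cols.append(col)
    return StainMatrix(np.column_stack(cols), DEFAULT_DYES, wl)


def default_white(wavelengths_nm=None, level: float = 4095.0) -> WhiteReference:
    """Flat white reference at ``level`` counts per band (12-bit full scale)."""
    wl = DEFAULT_WAVELENGTHS_NM if wavelengths_nm is None else np.asarray(wavelengths_nm)
    return WhiteReference(np.full(len(wl), float(level)))


@dataclass
class Cell:
    """One phantom cell: a nucleus ellipse inside a cytoplasm ellipse."""

    center: tuple[float, float]  # (row, col)
    cytoplasm_axes: tuple[float, float]  # semi-axes in pixels (row, col)
    nucleus_axes: tuple[float, float]
    cytoplasm_amounts: Mapping[str, float]
    nucleus_amounts: Mapping[str, float]
    nucleus_offset: tuple[float, float] = (0.0, 0.0)


# residual stain left on washed glass; faint but nonzero, as on real slides
_DEFAULT_BACKGROUND = {"H": 0.010, "EY": 0.012, "LG": 0.008, "OG": 0.006}


@dataclass
class PhantomScene:
    """Scene specification: geometry, amounts, noise and quantization.

    ``photon_count`` is the expected photon number per band on clear glass;
    ``None`` disables shot noise.  ``bit_depth`` quantizes the rendered
    counts to an integer ADC; ``None`` keeps floats.  ``seed`` is mandatory
    so that every rendered phantom is reproducible bit-for-bit.
    """

    shape: tuple[int, int]
    cells: Sequence[Cell]
    seed: int
    background_amounts: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BACKGROUND)
    )
    photon_count: float | None = 1e4
    bit_depth: int | None = 12
    overlap_additive: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("scene seed is mandatory")
        h, w = self.shape
        if h < 1 or w < 1:
            raise ValidationError("scene shape must be positive")
        for amounts in [self.background_amounts] + [
            dict(c.cytoplasm_amounts) | dict(c.nucleus_amounts) for c in self.cells
        ]:
            if any(v < 0 for v in amounts.values()):
                raise ValidationError("dye amounts must be nonnegative")
        if self.photon_count is not None and self.photon_count <= 0:
            raise ValidationError("photon_count must be positive")
        if self.bit_depth is not None and not 1 <= int(self.bit_depth) <= 16:
            raise ValidationError("bit_depth must be in [1, 16]")


def _ellipse_mask(shape, center, axes) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    ar = max(float(axes[0]), 1e-9)
    ac = max(float(axes[1]), 1e-9)
    return ((rr - center[0]) / ar) ** 2 + ((cc - center[1]) / ac) ** 2 <= 1.0


def _amount_vector(amounts: Mapping[str, float], dye_names) -> np.ndarray:
    unknown = set(amounts) - set(dye_names)
    if unknown:
        raise ValidationError(f"unknown dye(s) in scene amounts: {sorted(unknown)}")
    return np.array([float(amounts.get(d, 0.0)) for d in dye_names])


def compose_scene(scene: PhantomScene, dye_names=DEFAULT_DYES):
    """Ground-truth amount map (H, W, M) and label map (H, W) of a scene.

    Compositing order is nucleus over cytoplasm over glass; with
    ``overlap_additive`` the cytoplasm of overlapping cells adds (the
    absorbances of stacked cells are additive under Lambert-Beer).
    """
    h, w = scene.shape
    m = len(dye_names)
    truth = np.broadcast_to(
        _amount_vector(scene.background_amounts, dye_names), (h, w, m)
    ).copy()
    labels = np.full((h, w), LABEL_GLASS, dtype=np.uint8)
    for cell in scene.cells:
        cyto = _ellipse_mask((h, w), cell.center, cell.cytoplasm_axes)
        camounts = _amount_vector(cell.cytoplasm_amounts, dye_names)
        if scene.overlap_additive:
            prior = labels[cyto] != LABEL_GLASS
            truth[cyto] = np.where(
                prior[:, None], truth[cyto] + camounts, camounts
            )
        else:
            truth[cyto] = camounts
        labels[cyto] = LABEL_CYTOPLASM
    for cell in scene.cells:  # nuclei always paint on top
        ncenter = (
            cell.center[0] + cell.nucleus_offset[0],
            cell.center[1] + cell.nucleus_offset[1],
        )
        nuc = _ellipse_mask((h, w), ncenter, cell.nucleus_axes)
        truth[nuc] = _amount_vector(cell.nucleus_amounts, dye_names)
        labels[nuc] = LABEL_NUCLEUS
    return truth, labels


def render_phantom(
    scene: PhantomScene,
    stains: StainMatrix | None = None,
    white: WhiteReference | None = None,
):
    """Render a scene to (MSImage, ground-truth DyeAmountMap, label map).

    The clean observation is ``g = g0 * 10**(-H c)``; shot noise replaces
    each band value by a Poisson draw at the scene's photon budget (scaled
    back to camera units), and quantization rounds to integer counts
    clipped at the ADC full scale.
    """
    if stains is None:
        stains = default_spectra()
    if white is None:
        level = float(2 ** int(scene.bit_depth) - 1) if scene.bit_depth else 4095.0
        white = default_white(stains.wavelengths_nm, level)
    truth, labels = compose_scene(scene, stains.dye_names)
    truth_map = DyeAmountMap(truth, stains.dye_names, normalized=False)
    clean = forward_model(truth_map, stains, white)
    g = clean.data
    if scene.photon_count is not None:
        rng = np.random.default_rng(scene.seed)
        trans = g / white.g0[np.newaxis, np.newaxis, :]
        photons = rng.poisson(scene.photon_count * trans)
        g = photons / scene.photon_count * white.g0[np.newaxis, np.newaxis, :]
    if scene.bit_depth is not None:
        g = np.clip(np.round(g), 0.0, float(2 ** int(scene.bit_depth) - 1))
    return MSImage(g, stains.wavelengths_nm), truth_map, labels


def single_stain_absorbances(
    dye: str,
    n_pixels: int,
    seed: int,
    stains: StainMatrix | None = None,
    abundance_range: tuple[float, float] = (0.4, 1.6),
    photon_count: float | None = 1e4,
    white_level: float = 4095.0,
    floor: float = 1.0,
) -> np.ndarray:
    """Noisy absorbance vectors of a single-stain calibration specimen.

    Each pixel carries the chosen dye at a uniformly drawn abundance; the
    observation passes through the forward model, Poisson shot noise and
    the absorbance computation, mimicking a single-stain field used for
    stain-matrix calibration.  Returns an (n_pixels, N) array.
    """
    if stains is None:
        stains = default_spectra()
    if dye not in stains.dye_names:
        raise ValidationError(f"unknown dye {dye!r}")
    rng = np.random.default_rng(seed)
    beta = rng.uniform(*abundance_range, size=n_pixels)
    amounts = np.zeros((n_pixels, 1, stains.n_dyes))
    amounts[:, 0, stains.dye_names.index(dye)] = beta
    white = default_white(stains.wavelengths_nm, white_level)
    img = forward_model(
        DyeAmountMap(amounts, stains.dye_names), stains, white
    )
    g = img.data
    if photon_count is not None:
        trans = g / white.g0
        g = rng.poisson(photon_count * trans) / photon_count * white.g0
    noisy = MSImage(np.maximum(g, 0.0), stains.wavelengths_nm)
    return compute_absorbance(noisy, white, floor=floor).data[:, 0, :]


@dataclass
class TwoClassEffect:
    """Class means and spread of the patch-feature generator.

    Defaults emulate the clinical contrast between normal endocervical
    mucin and LEGH mucin on the normalized-amount scale: EC patches are
    EY-rich and essentially OG-free (pink acid mucin), LEGH patches are
    OG-rich with reduced EY (yellow gastric-type mucin), hematoxylin is
    near zero in both (mucin areas exclude nuclei), and light green is
    moderate with a mild LEGH excess.
    """

    ec_mean_amounts: Mapping[str, float] = field(
        default_factory=lambda: {"H": 0.01, "EY": 0.45, "LG": 0.12, "OG": 0.01}
    )
    legh_mean_amounts: Mapping[str, float] = field(
        default_factory=lambda: {"H": 0.01, "EY": 0.18, "LG": 0.20, "OG": 0.35}
    )
    spread: float = 0.08

    def __post_init__(self) -> None:
        if self.spread < 0:
            raise ValidationError("spread must be nonnegative")


def make_two_class_dataset(
    n_ec: int,
    n_legh: int,
    effect: TwoClassEffect | None = None,
    seed: int = 0,
    dye_names=DEFAULT_DYES,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-patch mean dye amounts for a labeled EC/LEGH sample.

    Features are drawn around the class means with isotropic Gaussian
    spread and clipped at zero (amounts are nonnegative).  Returns a
    DataFrame with one column per dye and the aligned label array.
    """
    if n_ec < 1 or n_legh < 1:
        raise ValidationError("need at least one sample per class")
    effect = effect or TwoClassEffect()
    rng = np.random.default_rng(seed)
    mu_ec = _amount_vector(effect.ec_mean_amounts, dye_names)
    mu_legh = _amount_vector(effect.legh_mean_amounts, dye_names)
    x_ec = mu_ec + effect.spread * rng.standard_normal((n_ec, len(dye_names)))
    x_legh = mu_legh + effect.spread * rng.standard_normal((n_legh, len(dye_names)))
    x = np.clip(np.vstack([x_ec, x_legh]), 0.0, None)
    y = np.array(["EC"] * n_ec + ["LEGH"] * n_legh, dtype=object)
    return pd.DataFrame(x, columns=list(dye_names)), y
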