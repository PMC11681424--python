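"""Approximate sRGB rendering of multispectral stacks for visual QC.

The per-band transmittance T_k = g_k / g0_k is linearly interpolated onto a
5-nm grid, weighted by a daylight illuminant and the CIE 1931 2-degree
color-matching functions to obtain XYZ, mapped to linear sRGB, white
balanced so that clear glass (T = 1) renders as exact white, and gamma
encoded.  Faithful colorimetry is *not* the goal — the render exists so a
user can pick glass/background regions and eyeball the unmixing — so the
CMFs use the standard piecewise-Gaussian analytic fit and the illuminant is
a 6504 K Planckian approximation of D65; the per-channel white balance
makes the result insensitive to both choices and to overall exposure.
"""

from __future__ import annotations

import warnings

import numpy as np

from .errors import DimensionError, ValidationError
from .types import MSImage, RGBImage, WhiteReference

__all__ = ["cie1931_cmf", "ms_to_srgb", "srgb_features"]

# XYZ (D65) -> linear sRGB
_XYZ_TO_SRGB = np.array(
    [
        [3.2406, -1.5372, -0.4986],
        [-0.9689, 1.8758, 0.0415],
        [0.0557, -0.2040, 1.0570],
    ]
)

_VISIBLE_NM = (380.0, 780.0)


def _lobe(wl, scale, mu, tau_lo, tau_hi):
    # piecewise Gaussian: different widths left/right of the peak
    tau = np.where(wl < mu, tau_lo, tau_hi)
    return scale * np.exp(-0.5 * (tau * (wl - mu)) ** 2)


def cie1931_cmf(wavelengths_nm) -> np.ndarray:
    """CIE 1931 2-degree color-matching functions, analytic multi-lobe fit.

    Returns an (n, 3) array of (xbar, ybar, zbar) sampled at the given
    wavelengths.  Accurate to about 1% of peak, ample for QC rendering.
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    x = (
        _lobe(wl, 0.362, 442.0, 0.0624, 0.0374)
        + _lobe(wl, 1.056, 599.8, 0.0264, 0.0323)
        + _lobe(wl, -0.065, 501.1, 0.0490, 0.0382)
    )
    y = _lobe(wl, 0.821, 568.8, 0.0213, 0.0247) + _lobe(
        wl, 0.286, 530.9, 0.0613, 0.0322
    )
    z = _lobe(wl, 1.217, 437.0, 0.0845, 0.0278) + _lobe(
        wl, 0.681, 459.0, 0.0385, 0.0725
    )
    return np.stack([np.clip(x, 0, None), np.clip(y, 0, None), np.clip(z, 0, None)], axis=-1)


def _daylight(wl_nm: np.ndarray, temperature_k: float = 6504.0) -> np.ndarray:
    """Planckian spectrum as a smooth daylight (D65-like) approximation."""
    wl_m = wl_nm * 1e-9
    c2 = 1.4388e-2  # second radiation constant, m*K
    s = wl_m**-5 / (np.exp(c2 / (wl_m * temperature_k)) - 1.0)
    return s / s.max()


def _gamma_encode(linear: np.ndarray) -> np.ndarray:
    lo = linear <= 0.0031308
    out = np.empty_like(linear)
    out[lo] = 12.92 * linear[lo]
    out[~lo] = 1.055 * np.power(linear[~lo], 1.0 / 2.4) - 0.055
    return out


def ms_to_srgb(image: MSImage, white: WhiteReference, grid_step_nm: float = 5.0) -> RGBImage:
    """Render a multispectral stack to a gamma-encoded sRGB image in [0, 1].

    Bands outside the visible range (380-780 nm) are dropped with a
    warning.  The render is ratio-invariant: scaling ``g`` and ``g0``
    together leaves it unchanged.
    """
    if image.n_bands != white.n_bands:
        raise DimensionError("image and white reference band counts differ")
    wl = image.wavelengths_nm
    visible = (wl >= _VISIBLE_NM[0]) & (wl <= _VISIBLE_NM[1])
    if not visible.any():
        raise ValidationError("no bands within the visible range 380-780 nm")
    if not visible.all():
        warnings.warn(
            f"ignoring {int((~visible).sum())} band(s) outside 380-780 nm",
            stacklevel=2,
        )
    wl = wl[visible]
    trans = np.clip(image.data[:, :, visible] / white.g0[visible], 0.0, None)

    grid = np.arange(_VISIBLE_NM[0], _VISIBLE_NM[1] + 0.5 * grid_step_nm, grid_step_nm)
    # linear interpolation (edge-extended) as a fixed (N, G) matrix
    basis = np.eye(wl.size)
    interp = np.stack([np.interp(grid, wl, basis[k]) for k in range(wl.size)])

    weights = cie1931_cmf(grid) * _daylight(grid)[:, np.newaxis]  # (G, 3)
    h, w, n = trans.shape
    xyz = (trans.reshape(-1, n) @ interp) @ weights  # (pixels, 3)
    xyz_white = weights.sum(axis=0)

    rgb_lin = xyz @ _XYZ_TO_SRGB.T
    white_lin = xyz_white @ _XYZ_TO_SRGB.T  # all positive for any sane illuminant
    rgb_lin = np.clip(rgb_lin / white_lin, 0.0, 1.0)
    rgb = np.clip(_gamma_encode(rgb_lin), 0.0, 1.0).reshape(h, w, 3)
    return RGBImage(rgb)


def srgb_features(rgb: RGBImage, mask: np.ndarray) -> np.ndarray:
    """Mean gamma-encoded (R, G, B) over the masked pixels, in [0, 1]."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != rgb.data.shape[:2]:
        raise DimensionError("mask shape does not match image")
    if not mask.any():
        raise ValidationError("empty patch mask")
    return rgb.data[mask].mean(axis=0)
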