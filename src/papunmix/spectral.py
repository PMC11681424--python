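"""Lambert-Beer forward model and per-pixel linear unmixing.

A transmitted-light specimen stained with M dyes attenuates band k of the
illumination as

    g_k = g0_k * 10**(-a_k),      a_k = sum_i c_i * eps_i(lambda_k),

where ``c_i`` is the amount of dye i at the pixel and ``eps_i`` its spectral
absorption coefficient at the band center (narrowband sensitivities are
approximated as delta functions).  Stacking bands gives ``a = H c`` with the
stain matrix ``H``; with more bands than dyes (M < N) the dye amounts are
the least-squares solution ``c = pinv(H) a`` per pixel.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DimensionError, SingularStainMatrixError, ValidationError
from .types import AbsorbanceImage, DyeAmountMap, MSImage, StainMatrix, WhiteReference

__all__ = [
    "compute_absorbance",
    "forward_model",
    "unmix",
    "unmix_pixels",
    "StainUnmixer",
]

#: Condition-number limit above which a stain matrix is treated as rank
#: deficient for unmixing purposes.
COND_LIMIT = 1e8


def _check_bands(n_image: int, n_other: int, what: str) -> None:
    if n_image != n_other:
        raise DimensionError(
            f"band-count mismatch: image has {n_image} bands, {what} has {n_other}"
        )


def compute_absorbance(
    image: MSImage, white: WhiteReference, floor: float = 1.0
) -> AbsorbanceImage:
    """Per-band optical density a = log10(g0 / max(g, floor)).

    Parameters
    ----------
    image
        Observed multi-band stack.
    white
        Per-band glass intensities g0 (same camera units as ``image``).
    floor
        Lower clip on the observed intensity before the log, in camera
        counts.  Dark or saturated-to-zero pixels would otherwise produce
        infinite absorbance; one count is the smallest distinguishable
        nonzero signal of an integer ADC.

    Notes
    -----
    Intensities above the white reference (possible under shot noise on
    nearly clear glass) yield small *negative* absorbances.  They are kept
    as-is so that the least-squares unmixing can average the noise out
    rather than being biased upward by one-sided clipping.
    """
    if floor <= 0:
        raise ValidationError("floor must be positive")
    _check_bands(image.n_bands, white.n_bands, "white reference")
    g = np.maximum(image.data, floor)
    alpha = np.log10(white.g0[np.newaxis, np.newaxis, :] / g)
    return AbsorbanceImage(alpha, image.wavelengths_nm)


def forward_model(
    amounts: DyeAmountMap, stains: StainMatrix, white: WhiteReference
) -> MSImage:
    """Render the noiseless observation g = g0 * 10**(-H c) of a dye map."""
    if tuple(amounts.dye_names) != tuple(stains.dye_names):
        raise ValidationError(
            f"dye sets differ: map has {list(amounts.dye_names)}, "
            f"matrix has {list(stains.dye_names)}"
        )
    _check_bands(stains.n_bands, white.n_bands, "white reference")
    if np.any(amounts.data < 0):
        warnings.warn(
            "negative dye amounts in forward model; the rendered intensities "
            "will exceed the white reference in some bands",
            stacklevel=2,
        )
    od = amounts.data @ stains.coefficients.T  # (H, W, N)
    g = white.g0[np.newaxis, np.newaxis, :] * np.power(10.0, -od)
    return MSImage(g, stains.wavelengths_nm)


def _check_rank(stains: StainMatrix) -> None:
    cond = stains.condition_number()
    if not np.isfinite(cond) or cond > COND_LIMIT:
        # identify the most collinear pair for the error message
        gram = np.abs(stains.coefficients.T @ stains.coefficients)
        np.fill_diagonal(gram, 0.0)
        i, j = np.unravel_index(np.argmax(gram), gram.shape)
        raise SingularStainMatrixError(
            f"stain matrix is rank deficient (condition number {cond:.3g}); "
            f"most collinear dyes: {stains.dye_names[i]} and {stains.dye_names[j]}"
        )


def unmix_pixels(
    absorbance: np.ndarray, stains: StainMatrix, clip_negative: bool = True
) -> np.ndarray:
    """Unmix a flat (n, N) array of absorbance vectors to (n, M) amounts."""
    a = np.asarray(absorbance, dtype=float)
    _check_bands(a.shape[-1], stains.n_bands, "stain matrix")
    _check_rank(stains)
    pinv = np.linalg.pinv(stains.coefficients)  # (M, N)
    c = a @ pinv.T
    if clip_negative:
        c = np.clip(c, 0.0, None)
    return c


def unmix(
    absorbance: AbsorbanceImage, stains: StainMatrix, clip_negative: bool = True
) -> DyeAmountMap:
    """Per-pixel Moore-Penrose unmixing c = pinv(H) a.

    With ``clip_negative`` (the default) the least-squares solution is
    computed first and negative amounts are then set to zero; the solve is
    never constrained, so clipping does not perturb the other dyes.
    Returns raw (unnormalized) amounts.
    """
    c = unmix_pixels(absorbance.data, stains, clip_negative=clip_negative)
    return DyeAmountMap(c, dye_names=stains.dye_names, normalized=False)


class StainUnmixer(TransformerMixin, BaseEstimator):
    """Stain unmixing as a scikit-learn transformer over pixel vectors.

    ``fit(X, y)`` estimates one stain column per dye label from single-stain
    absorbance pixels (rows of ``X`` are length-N absorbance vectors, ``y``
    the dye name each pixel came from); ``transform(X)`` maps absorbance
    vectors to dye amounts with the fitted matrix.  A pre-computed
    :class:`~papunmix.types.StainMatrix` may be supplied instead, in which
    case ``fit`` only validates it.

    Attributes
    ----------
    stain_matrix_ : StainMatrix
        Fitted (or adopted) stain matrix.
    condition_number_ : float
        Its 2-norm condition number.
    """

    def __init__(
        self,
        stains: StainMatrix | None = None,
        wavelengths_nm=None,
        clip_negative: bool = True,
    ):
        self.stains = stains
        self.wavelengths_nm = wavelengths_nm
        self.clip_negative = clip_negative

    def fit(self, X, y=None):
        from .calibration import build_stain_matrix, estimate_stain_vector

        if self.stains is not None:
            _check_rank(self.stains)
            self.stain_matrix_ = self.stains
        else:
            if y is None:
                raise ValidationError(
                    "fit requires dye labels y when no stain matrix is given"
                )
            X = np.asarray(X, dtype=float)
            y = np.asarray(y)
            if X.ndim != 2 or X.shape[0] != y.shape[0]:
                raise DimensionError("X must be (n_pixels, n_bands) aligned with y")
            dyes = list(dict.fromkeys(y.tolist()))  # first-appearance order
            wl = (
                np.asarray(self.wavelengths_nm, dtype=float)
                if self.wavelengths_nm is not None
                else np.arange(X.shape[1], dtype=float)
            )
            vectors = {d: estimate_stain_vector(X[y == d]) for d in dyes}
            self.stain_matrix_ = build_stain_matrix(vectors, wl)
        self.condition_number_ = self.stain_matrix_.condition_number()
        return self

    def transform(self, X):
        if not hasattr(self, "stain_matrix_"):
            raise ValidationError("StainUnmixer is not fitted")
        return unmix_pixels(
            np.asarray(X, dtype=float),
            self.stain_matrix_,
            clip_negative=self.clip_negative,
        )
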