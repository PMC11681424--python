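"""Core container types for the multispectral unmixing pipeline.

The pipeline is built around four array containers:

``MSImage``
    An H x W x N stack of per-band transmitted-light intensities g_k in
    arbitrary camera units, with the band center wavelengths attached.
``AbsorbanceImage``
    The per-band optical density a_k = log10(g0_k / g_k) of a stack,
    relative to a per-band white (clear glass) reference.
``StainMatrix``
    The N x M matrix whose columns are the unit-norm spectral absorption
    coefficient vectors of the M dyes; under the Lambert-Beer model the
    absorbance of a mixed pixel is the matrix applied to its dye amounts.
``DyeAmountMap``
    The H x W x M per-pixel dye amounts recovered by unmixing, either raw
    (relative units) or normalized by per-dye reference values.

All containers validate their invariants on construction and are otherwise
plain ``numpy`` array holders; the arrays they wrap are not copied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DimensionError, ValidationError

#: Dye ordering used throughout: hematoxylin, eosin Y, light green SF,
#: orange G.  Bismarck brown is excluded from the active dye set (its
#: phospholipid target is irrelevant to mucin analysis and its uptake is
#: too faint to calibrate reliably).
DEFAULT_DYES: tuple[str, ...] = ("H", "EY", "LG", "OG")

#: Default band grid of the 14-band acquisition protocol: band centers
#: from 440 to 700 nm at 20-nm intervals (the bands tile 440-720 nm).
DEFAULT_WAVELENGTHS_NM: np.ndarray = np.arange(440.0, 701.0, 20.0)


def _as_wavelengths(wavelengths_nm: Sequence[float]) -> np.ndarray:
    wl = np.asarray(wavelengths_nm, dtype=float)
    if wl.ndim != 1 or wl.size < 1:
        raise ValidationError("wavelengths_nm must be a non-empty 1-D sequence")
    if wl.size > 1 and not np.all(np.diff(wl) > 0):
        raise ValidationError("wavelengths_nm must be strictly increasing")
    return wl


@dataclass
class MSImage:
    """Multi-band intensity stack (H, W, N) with band wavelengths in nm."""

    data: np.ndarray
    wavelengths_nm: np.ndarray
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise DimensionError(
                f"MSImage data must be (H, W, N), got shape {self.data.shape}"
            )
        if np.any(self.data < 0):
            raise ValidationError("MSImage intensities must be nonnegative")
        self.wavelengths_nm = _as_wavelengths(self.wavelengths_nm)
        if self.data.shape[2] != self.wavelengths_nm.size:
            raise DimensionError(
                f"band count {self.data.shape[2]} does not match "
                f"{self.wavelengths_nm.size} wavelengths"
            )
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape (H, W)."""
        return self.data.shape[:2]


@dataclass
class WhiteReference:
    """Per-band intensity of clear glass (the incident-light reference g0)."""

    g0: np.ndarray

    def __post_init__(self) -> None:
        self.g0 = np.asarray(self.g0, dtype=float).ravel()
        if self.g0.size < 1:
            raise ValidationError("white reference must have at least one band")
        if np.any(self.g0 <= 0):
            raise ValidationError("white reference intensities must be positive")

    @property
    def n_bands(self) -> int:
        return self.g0.size


@dataclass
class AbsorbanceImage:
    """Per-band base-10 optical density stack (H, W, N)."""

    data: np.ndarray
    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise DimensionError(
                f"AbsorbanceImage data must be (H, W, N), got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError(
                "absorbance must be finite everywhere; clip saturated or "
                "zero intensities before taking the log"
            )
        self.wavelengths_nm = _as_wavelengths(self.wavelengths_nm)
        if self.data.shape[2] != self.wavelengths_nm.size:
            raise DimensionError("band count does not match wavelengths")

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class StainMatrix:
    """N x M matrix of per-band spectral absorption coefficients.

    Columns are the dye signatures; they are renormalized to unit Euclidean
    norm on construction (the scale of a signature is arbitrary because
    single-stain calibration only fixes it up to the unknown dye abundance).
    Requires more bands than dyes (M < N) so that unmixing is overdetermined.
    """

    coefficients: np.ndarray
    dye_names: tuple[str, ...] = DEFAULT_DYES
    wavelengths_nm: np.ndarray = field(default_factory=lambda: DEFAULT_WAVELENGTHS_NM.copy())

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.dye_names = tuple(self.dye_names)
        if self.coefficients.ndim != 2:
            raise DimensionError("stain matrix must be 2-D (bands x dyes)")
        n, m = self.coefficients.shape
        if m != len(self.dye_names):
            raise DimensionError(
                f"{m} columns but {len(self.dye_names)} dye names"
            )
        if len(set(self.dye_names)) != m:
            raise ValidationError("dye names must be unique")
        if m >= n:
            raise ValidationError(
                f"need more bands than dyes for unmixing (got N={n}, M={m})"
            )
        if np.any(self.coefficients < -1e-12):
            raise ValidationError("absorption coefficients must be nonnegative")
        self.coefficients = np.clip(self.coefficients, 0.0, None)
        norms = np.linalg.norm(self.coefficients, axis=0)
        if np.any(norms == 0):
            dead = [d for d, nz in zip(self.dye_names, norms) if nz == 0]
            raise ValidationError(f"all-zero stain column(s): {dead}")
        self.coefficients = self.coefficients / norms
        self.wavelengths_nm = _as_wavelengths(self.wavelengths_nm)
        if self.wavelengths_nm.size != n:
            raise DimensionError("row count does not match wavelengths")

    @property
    def n_bands(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_dyes(self) -> int:
        return self.coefficients.shape[1]

    def condition_number(self) -> float:
        """2-norm condition number of the matrix (collinearity diagnostic)."""
        return float(np.linalg.cond(self.coefficients))

    def column(self, dye: str) -> np.ndarray:
        try:
            j = self.dye_names.index(dye)
        except ValueError:
            raise ValidationError(
                f"unknown dye {dye!r}; matrix has {list(self.dye_names)}"
            ) from None
        return self.coefficients[:, j]


@dataclass
class DyeAmountMap:
    """Per-pixel dye amounts (H, W, M), raw or reference-normalized."""

    data: np.ndarray
    dye_names: tuple[str, ...] = DEFAULT_DYES
    normalized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.dye_names = tuple(self.dye_names)
        if self.data.ndim != 3:
            raise DimensionError("DyeAmountMap data must be (H, W, M)")
        if self.data.shape[2] != len(self.dye_names):
            raise DimensionError(
                f"{self.data.shape[2]} planes but {len(self.dye_names)} dye names"
            )

    @property
    def n_dyes(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def plane(self, dye: str) -> np.ndarray:
        """Return the (H, W) amount plane of one dye."""
        try:
            j = self.dye_names.index(dye)
        except ValueError:
            raise ValidationError(
                f"unknown dye {dye!r}; map has {list(self.dye_names)}"
            ) from None
        return self.data[:, :, j]


@dataclass
class RGBImage:
    """Gamma-encoded sRGB render (H, W, 3), channels in [0, 1]."""

    data: np.ndarray
    provenance: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise DimensionError("RGBImage data must be (H, W, 3)")
        if np.any(self.data < 0) or np.any(self.data > 1):
            raise ValidationError("sRGB channels must lie in [0, 1]")
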