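"""Stain-matrix calibration, amount normalization and background masking.

Calibration uses single-stain specimens: a pixel stained with dye l alone
has absorbance ``a = beta * eps_l`` with unknown abundance ``beta``, so each
pixel fixes the *direction* of the dye's spectral signature.  Pixels are
normalized to unit Euclidean norm, averaged, and renormalized; the average
suppresses shot noise while the per-pixel normalization removes the
abundance nuisance.

Normalization of unmixed amounts divides each dye plane by a per-dye
reference value (a high percentile of the amounts in manually selected
well-stained regions), so that a well-stained nucleus carries about one
unit of hematoxylin and well-stained cytoplasm about one unit of its dye.

Background elimination exploits that bare glass retains only faint residual
stain: per-dye thresholds are read off a user-selected background region,
and a pixel is background iff *every* dye amount falls below its threshold.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np

from .errors import DimensionError, ValidationError
from .types import DyeAmountMap, StainMatrix

__all__ = [
    "ReferenceValues",
    "BackgroundThresholds",
    "estimate_stain_vector",
    "build_stain_matrix",
    "compute_reference_values",
    "normalize_amounts",
    "derive_background_thresholds",
    "apply_background_mask",
    "preset_reference_values",
]

logger = logging.getLogger(__name__)

#: Fewer calibration pixels than this triggers a warning (a 5x5 sample is
#: the customary minimum per single-stain field).
MIN_CALIBRATION_PIXELS = 25


@dataclass
class ReferenceValues:
    """Per-dye normalization denominators q_l (positive reals)."""

    q: dict[str, float]

    def __post_init__(self) -> None:
        self.q = {str(k): float(v) for k, v in self.q.items()}
        if not self.q:
            raise ValidationError("reference values must cover at least one dye")
        bad = {k: v for k, v in self.q.items() if not v > 0}
        if bad:
            raise ValidationError(f"reference values must be positive: {bad}")

    def as_vector(self, dye_names) -> np.ndarray:
        missing = [d for d in dye_names if d not in self.q]
        if missing:
            raise ValidationError(f"missing reference value for dye(s): {missing}")
        return np.array([self.q[d] for d in dye_names], dtype=float)


@dataclass
class BackgroundThresholds:
    """Per-dye background thresholds t_l (nonnegative reals)."""

    t: dict[str, float]

    def __post_init__(self) -> None:
        self.t = {str(k): float(v) for k, v in self.t.items()}
        if not self.t:
            raise ValidationError("thresholds must cover at least one dye")
        bad = {k: v for k, v in self.t.items() if v < 0}
        if bad:
            raise ValidationError(f"thresholds must be nonnegative: {bad}")

    def as_vector(self, dye_names) -> np.ndarray:
        missing = [d for d in dye_names if d not in self.t]
        if missing:
            raise ValidationError(f"missing threshold for dye(s): {missing}")
        return np.array([self.t[d] for d in dye_names], dtype=float)


def estimate_stain_vector(pixels) -> np.ndarray:
    """Estimate one unit-norm stain column from single-stain absorbances.

    Each length-N absorbance vector is scaled to unit Euclidean norm (its
    magnitude is the unknown dye abundance), the unit vectors are averaged,
    and the mean is renormalized.  All-zero pixels are skipped with a
    warning; an estimate with negative entries (possible under heavy noise)
    is also flagged.
    """
    a = np.atleast_2d(np.asarray(pixels, dtype=float))
    if a.size == 0 or a.shape[0] < 1:
        raise ValidationError("need at least one calibration pixel")
    norms = np.linalg.norm(a, axis=1)
    nonzero = norms > 0
    if not np.all(nonzero):
        warnings.warn(
            f"skipping {int((~nonzero).sum())} all-zero calibration pixel(s)",
            stacklevel=2,
        )
        a, norms = a[nonzero], norms[nonzero]
    if a.shape[0] == 0:
        raise ValidationError("all calibration pixels were zero")
    if a.shape[0] < MIN_CALIBRATION_PIXELS:
        warnings.warn(
            f"only {a.shape[0]} calibration pixels (fewer than "
            f"{MIN_CALIBRATION_PIXELS}); the estimate may be noisy",
            stacklevel=2,
        )
    mean = (a / norms[:, np.newaxis]).mean(axis=0)
    mean_norm = np.linalg.norm(mean)
    if mean_norm == 0:
        raise ValidationError("calibration pixels cancel; cannot normalize")
    vec = mean / mean_norm
    # noise makes near-zero entries dip slightly negative; only warn when
    # the negativity is a meaningful fraction of the unit-norm estimate
    if np.any(vec < -0.01):
        warnings.warn(
            "estimated stain vector has negative entries; check that the "
            "calibration pixels are truly single-stained",
            stacklevel=2,
        )
    return vec


def build_stain_matrix(
    vectors: Mapping[str, np.ndarray],
    wavelengths_nm,
    max_condition: float = 1e6,
) -> StainMatrix:
    """Assemble estimated dye columns into a stain matrix.

    Columns are ordered as given.  Raises
    :class:`~papunmix.errors.SingularStainMatrixError` (via the
    :class:`~papunmix.types.StainMatrix` rank check) when the columns are
    collinear beyond ``max_condition``.
    """
    if len(vectors) < 2:
        raise ValidationError("need at least two dyes to build a stain matrix")
    names = tuple(vectors.keys())
    cols = [np.asarray(v, dtype=float).ravel() for v in vectors.values()]
    lengths = {c.size for c in cols}
    if len(lengths) != 1:
        raise DimensionError(f"stain vectors have differing lengths: {lengths}")
    matrix = StainMatrix(
        np.clip(np.column_stack(cols), 0.0, None),
        dye_names=names,
        wavelengths_nm=wavelengths_nm,
    )
    cond = matrix.condition_number()
    logger.info(
        "stain matrix: %d bands x %d dyes, condition number %.4g",
        matrix.n_bands,
        matrix.n_dyes,
        cond,
    )
    if not np.isfinite(cond) or cond > max_condition:
        from .errors import SingularStainMatrixError

        gram = np.abs(matrix.coefficients.T @ matrix.coefficients)
        np.fill_diagonal(gram, 0.0)
        i, j = np.unravel_index(np.argmax(gram), gram.shape)
        raise SingularStainMatrixError(
            f"condition number {cond:.4g} exceeds {max_condition:.4g}; "
            f"most collinear dyes: {names[i]} and {names[j]}"
        )
    return matrix


def _masked_percentile(
    amounts: DyeAmountMap, dye: str, mask: np.ndarray, percentile: float
) -> float:
    plane = amounts.plane(dye)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != plane.shape:
        raise DimensionError(
            f"mask shape {mask.shape} does not match map shape {plane.shape}"
        )
    if not mask.any():
        raise ValidationError(f"empty region mask for dye {dye!r}")
    return float(np.percentile(plane[mask], percentile))


def compute_reference_values(
    amounts: DyeAmountMap,
    regions: Mapping[str, np.ndarray],
    percentile: float = 99.0,
) -> ReferenceValues:
    """Per-dye reference values: a high percentile of the amounts inside
    that dye's well-stained region mask (default: the 99th percentile, a
    robust stand-in for the maximum well-stained amount)."""
    return ReferenceValues(
        {d: _masked_percentile(amounts, d, m, percentile) for d, m in regions.items()}
    )


def normalize_amounts(amounts: DyeAmountMap, refs: ReferenceValues) -> DyeAmountMap:
    """Divide each dye plane by its reference value and set the flag."""
    if amounts.normalized:
        raise ValidationError("amounts are already normalized")
    q = refs.as_vector(amounts.dye_names)
    return DyeAmountMap(
        amounts.data / q[np.newaxis, np.newaxis, :],
        dye_names=amounts.dye_names,
        normalized=True,
    )


def derive_background_thresholds(
    amounts: DyeAmountMap,
    background_mask: np.ndarray,
    percentile: float = 99.0,
) -> BackgroundThresholds:
    """Per-dye thresholds t_l from a user-selected background region.

    The threshold is a high percentile of each dye's amounts over the
    region, capturing the residual stain left on bare glass by imperfect
    washing.  Thresholds live on the same scale (raw or normalized) as the
    amounts they were derived from.
    """
    return BackgroundThresholds(
        {
            d: _masked_percentile(amounts, d, background_mask, percentile)
            for d in amounts.dye_names
        }
    )


def apply_background_mask(
    amounts: DyeAmountMap, thresholds: BackgroundThresholds
) -> np.ndarray:
    """Boolean (H, W) mask of stained pixels.

    A pixel is background iff *all* dye amounts are strictly below their
    thresholds; the returned mask marks the complement (stained pixels,
    i.e. at least one dye at or above threshold).
    """
    t = thresholds.as_vector(amounts.dye_names)
    return np.any(amounts.data >= t[np.newaxis, np.newaxis, :], axis=-1)


def preset_reference_values() -> ReferenceValues:
    """Bundled reference values for the 14-band Papanicolaou protocol.

    These are fixed calibration constants measured on well-stained clinical
    material (99th-percentile amounts of manually selected nuclei and
    cytoplasm regions); the underlying specimens are not distributed.
    """
    text = (
        resources.files("papunmix").joinpath("presets/reference_values.json").read_text()
    )
    return ReferenceValues(json.loads(text))
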