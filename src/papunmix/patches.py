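"""Patch tiling, categorization and per-patch mean dye amounts.

Dye-amount maps are tiled into non-overlapping square patches (default
10 x 10 pixels) and each patch is assigned one of three labels:

``nucleus``
    more than half of its pixels carry hematoxylin at or above the
    background threshold;
``background``
    more than ``b_percent`` of its pixels are non-stained (every dye below
    its threshold);
``mucin``
    everything else — the cytoplasm/mucin patches that feed the EC-vs-LEGH
    discriminant.

The nucleus test is applied first, then the background test.  Per-patch
features are the mean dye amounts over the *stained* pixels only, so a
half-empty patch is not diluted toward zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import BackgroundThresholds
from .errors import ValidationError
from .types import DyeAmountMap

__all__ = [
    "Patch",
    "tile",
    "categorize_patch",
    "patch_mean_amounts",
    "analyze_patches",
    "patches_to_frame",
]

LABELS = ("nucleus", "background", "mucin", "unassigned")


@dataclass
class Patch:
    """One tile of a dye-amount map."""

    origin: tuple[int, int]  # (row, col), 0-based top-left
    size: int = 10
    label: str = "unassigned"
    mean_amounts: np.ndarray | None = field(default=None, repr=False)
    predicted: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValidationError("patch size must be >= 1")
        if self.label not in LABELS:
            raise ValidationError(f"unknown patch label {self.label!r}")

    def slices(self) -> tuple[slice, slice]:
        r, c = self.origin
        return slice(r, r + self.size), slice(c, c + self.size)


def tile(shape: tuple[int, int], patch_size: int = 10) -> list[Patch]:
    """Non-overlapping grid of patches anchored at (0, 0).

    Right/bottom remainders narrower than ``patch_size`` are discarded.
    """
    if patch_size < 1:
        raise ValidationError("patch_size must be >= 1")
    h, w = int(shape[0]), int(shape[1])
    return [
        Patch(origin=(r * patch_size, c * patch_size), size=patch_size)
        for r in range(h // patch_size)
        for c in range(w // patch_size)
    ]


def _stain_flags(
    patch_amounts: np.ndarray,
    dye_names,
    thresholds: BackgroundThresholds,
    h_dye: str,
):
    dye_names = tuple(dye_names)
    if h_dye not in dye_names:
        raise ValidationError(f"unknown nuclear dye {h_dye!r}; have {list(dye_names)}")
    t = thresholds.as_vector(dye_names)
    a = np.asarray(patch_amounts, dtype=float)
    h_stained = a[..., dye_names.index(h_dye)] >= t[dye_names.index(h_dye)]
    nonstained = np.all(a < t, axis=-1)
    return h_stained, nonstained


def categorize_patch(
    patch_amounts: np.ndarray,
    dye_names,
    thresholds: BackgroundThresholds,
    h_dye: str = "H",
    b_percent: float = 90.0,
) -> str:
    """Label one patch as nucleus, background or mucin.

    A pixel is H-stained when its hematoxylin amount is at or above the
    hematoxylin background threshold, and non-stained when every dye is
    below its threshold.  Strictly more than 50% H-stained pixels makes a
    nucleus patch (a 10x10 patch needs 51); otherwise strictly more than
    ``b_percent`` non-stained pixels makes a background patch; anything
    else is mucin.
    """
    if not 0 <= b_percent <= 100:
        raise ValidationError("b_percent must be within [0, 100]")
    h_stained, nonstained = _stain_flags(patch_amounts, dye_names, thresholds, h_dye)
    n_pix = h_stained.size
    if h_stained.sum() > 0.5 * n_pix:
        return "nucleus"
    if nonstained.sum() > (b_percent / 100.0) * n_pix:
        return "background"
    return "mucin"


def patch_mean_amounts(
    patch_amounts: np.ndarray,
    dye_names,
    thresholds: BackgroundThresholds,
) -> np.ndarray | None:
    """Mean amount per dye over the stained pixels of a patch.

    Returns ``None`` when the patch contains no stained pixel (the empty
    marker propagates instead of a spurious zero vector).
    """
    _, nonstained = _stain_flags(
        patch_amounts, dye_names, thresholds, h_dye=tuple(dye_names)[0]
    )
    stained = ~nonstained
    if not stained.any():
        return None
    return np.asarray(patch_amounts, dtype=float)[stained].mean(axis=0)


def analyze_patches(
    amounts: DyeAmountMap,
    thresholds: BackgroundThresholds,
    patch_size: int = 10,
    h_dye: str = "H",
    b_percent: float = 90.0,
    model=None,
) -> list[Patch]:
    """Tile, categorize and featurize a whole dye-amount map.

    Mucin patches get ``mean_amounts``; when a discriminant ``model`` is
    given they additionally get a ``score`` and a ``predicted`` class
    (the model's features are looked up by dye name).
    """
    patches = tile(amounts.shape, patch_size)
    for p in patches:
        block = amounts.data[p.slices()]
        p.label = categorize_patch(block, amounts.dye_names, thresholds, h_dye, b_percent)
        if p.label != "mucin":
            continue
        p.mean_amounts = patch_mean_amounts(block, amounts.dye_names, thresholds)
        if model is not None and p.mean_amounts is not None:
            feats = _select_features(p.mean_amounts, amounts.dye_names, model.feature_names)
            p.score = float(model.decision(feats))
            p.predicted = model.classify(feats)
    return patches


def _select_features(mean_amounts, dye_names, feature_names) -> np.ndarray:
    dye_names = tuple(dye_names)
    missing = [f for f in feature_names if f not in dye_names]
    if missing:
        raise ValidationError(
            f"model feature(s) {missing} not among dyes {list(dye_names)}"
        )
    return np.array([mean_amounts[dye_names.index(f)] for f in feature_names])


def patches_to_frame(patches: list[Patch], dye_names) -> pd.DataFrame:
    """Tabulate patches (origin, label, per-dye means, score, prediction)."""
    dye_names = tuple(dye_names)
    rows = []
    for p in patches:
        row: dict = {
            "row": p.origin[0],
            "col": p.origin[1],
            "size": p.size,
            "label": p.label,
        }
        for j, d in enumerate(dye_names):
            row[f"mean_{d}"] = (
                float(p.mean_amounts[j]) if p.mean_amounts is not None else np.nan
            )
        row["score"] = p.score if p.score is not None else np.nan
        row["predicted"] = p.predicted if p.predicted is not None else ""
        rows.append(row)
    return pd.DataFrame(rows)
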