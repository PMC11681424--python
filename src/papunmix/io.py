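"""File formats: TIFF stacks, stain matrices, masks, JSON sidecars.

Multispectral stacks and dye-amount maps travel as multi-page TIFF (one
page per band or dye, ``tifffile`` conventions) with the band/dye metadata
embedded as JSON in the ImageDescription tag and mirrored in an optional
``<file>.json`` sidecar.  Stain matrices are CSV (wavelength column plus
one column per dye) or an equivalent JSON.  Region masks are either binary
PNG or JSON rectangle lists ``[col, row, width, height]`` (0-based,
half-open).  Reference values, thresholds and discriminant models are flat
JSON keyed by dye/feature name.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .calibration import BackgroundThresholds, ReferenceValues
from .discriminant import LinearDiscriminantModel
from .errors import ValidationError
from .types import DyeAmountMap, MSImage, StainMatrix, WhiteReference

__all__ = [
    "read_ms_tiff",
    "write_ms_tiff",
    "read_dye_maps",
    "write_dye_maps",
    "read_stain_matrix",
    "write_stain_matrix",
    "read_white_reference",
    "write_white_reference",
    "read_mask",
    "rects_to_mask",
    "read_reference_values",
    "write_reference_values",
    "read_thresholds",
    "write_thresholds",
    "read_model",
    "write_models",
]


def _read_metadata(path: Path, tif: tifffile.TiffFile) -> dict:
    desc = tif.pages[0].description
    if desc:
        try:
            meta = json.loads(desc)
            # tifffile writes a bare {"shape": ...} description by default;
            # only trust descriptions that carry our metadata keys
            if isinstance(meta, dict) and (
                "wavelengths_nm" in meta or "dye_names" in meta
            ):
                return meta
        except json.JSONDecodeError:
            pass
    sidecar = path.with_name(path.name + ".json")
    if sidecar.exists():
        return json.loads(sidecar.read_text())
    return {}


def write_ms_tiff(
    path, image: MSImage, sidecar: bool = False, dtype: str = "float32"
) -> None:
    """Write a stack as multi-page TIFF, one page per band, ascending
    wavelength; band centers go into the description tag (and optionally a
    sidecar JSON)."""
    path = Path(path)
    meta = {
        "wavelengths_nm": image.wavelengths_nm.tolist(),
        "pixel_size_um": image.pixel_size_um,
    }
    pages = np.moveaxis(image.data, -1, 0)
    if dtype == "uint16":
        pages = np.clip(np.round(pages), 0, 65535).astype(np.uint16)
    else:
        pages = pages.astype(np.float32)
    tifffile.imwrite(
        path, pages, description=json.dumps(meta), photometric="minisblack"
    )
    if sidecar:
        path.with_name(path.name + ".json").write_text(json.dumps(meta, indent=1))


def read_ms_tiff(path) -> MSImage:
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        meta = _read_metadata(path, tif)
    if pages.ndim == 2:
        pages = pages[np.newaxis]
    wl = meta.get("wavelengths_nm")
    if wl is None:
        raise ValidationError(
            f"{path}: no band wavelengths in description tag or sidecar JSON"
        )
    return MSImage(
        np.moveaxis(pages.astype(float), 0, -1),
        np.asarray(wl, dtype=float),
        pixel_size_um=meta.get("pixel_size_um"),
    )


def write_dye_maps(path, amounts: DyeAmountMap) -> None:
    """Write a dye-amount map as a multi-page float32 TIFF with dye names."""
    meta = {"dye_names": list(amounts.dye_names), "normalized": amounts.normalized}
    tifffile.imwrite(
        Path(path),
        np.moveaxis(amounts.data, -1, 0).astype(np.float32),
        description=json.dumps(meta),
        photometric="minisblack",
    )


def read_dye_maps(path) -> DyeAmountMap:
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        meta = _read_metadata(path, tif)
    if pages.ndim == 2:
        pages = pages[np.newaxis]
    names = meta.get("dye_names")
    if names is None:
        raise ValidationError(f"{path}: no dye names in metadata")
    return DyeAmountMap(
        np.moveaxis(pages.astype(float), 0, -1),
        tuple(names),
        normalized=bool(meta.get("normalized", False)),
    )


def write_stain_matrix(path, stains: StainMatrix) -> None:
    """CSV (wavelength_nm + dye columns) or JSON, chosen by extension."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "wavelengths_nm": stains.wavelengths_nm.tolist(),
            "dyes": {
                d: stains.coefficients[:, j].tolist()
                for j, d in enumerate(stains.dye_names)
            },
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        frame = pd.DataFrame(
            stains.coefficients, columns=list(stains.dye_names)
        )
        frame.insert(0, "wavelength_nm", stains.wavelengths_nm)
        frame.to_csv(path, index=False)


def read_stain_matrix(path) -> StainMatrix:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        names = tuple(payload["dyes"].keys())
        coeffs = np.column_stack([payload["dyes"][d] for d in names])
        wl = np.asarray(payload["wavelengths_nm"], dtype=float)
    else:
        frame = pd.read_csv(path)
        if "wavelength_nm" not in frame.columns:
            raise ValidationError(f"{path}: missing wavelength_nm column")
        wl = frame["wavelength_nm"].to_numpy(dtype=float)
        names = tuple(c for c in frame.columns if c != "wavelength_nm")
        coeffs = frame[list(names)].to_numpy(dtype=float)
    return StainMatrix(coeffs, names, wl)


def write_white_reference(path, white: WhiteReference) -> None:
    Path(path).write_text(json.dumps({"g0": white.g0.tolist()}, indent=1))


def read_white_reference(path) -> WhiteReference:
    payload = json.loads(Path(path).read_text())
    return WhiteReference(np.asarray(payload["g0"], dtype=float))


def rects_to_mask(rects: Sequence[Sequence[float]], shape) -> np.ndarray:
    """Rasterize ``[col, row, width, height]`` rectangles (half-open)."""
    mask = np.zeros(tuple(shape), dtype=bool)
    h, w = mask.shape
    for rect in rects:
        if len(rect) != 4:
            raise ValidationError(f"rectangle must be [x, y, w, h], got {rect}")
        x, y, rw, rh = (int(v) for v in rect)
        if rw <= 0 or rh <= 0:
            raise ValidationError(f"rectangle has nonpositive extent: {rect}")
        if x < 0 or y < 0 or x + rw > w or y + rh > h:
            raise ValidationError(
                f"rectangle {rect} falls outside image of shape {(h, w)}"
            )
        mask[y : y + rh, x : x + rw] = True
    return mask


def read_mask(path, shape=None) -> np.ndarray:
    """Binary mask from PNG (nonzero = selected) or rectangle-list JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        if shape is None:
            raise ValidationError("rectangle masks need the target image shape")
        return rects_to_mask(json.loads(path.read_text()), shape)
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    mask = arr > 0
    if shape is not None and mask.shape != tuple(shape):
        raise ValidationError(
            f"mask shape {mask.shape} does not match image shape {tuple(shape)}"
        )
    return mask


def _write_flat_json(path, mapping: Mapping[str, float]) -> None:
    Path(path).write_text(json.dumps(dict(mapping), indent=1))


def write_reference_values(path, refs: ReferenceValues) -> None:
    _write_flat_json(path, refs.q)


def read_reference_values(path) -> ReferenceValues:
    return ReferenceValues(json.loads(Path(path).read_text()))


def write_thresholds(path, thresholds: BackgroundThresholds) -> None:
    _write_flat_json(path, thresholds.t)


def read_thresholds(path) -> BackgroundThresholds:
    return BackgroundThresholds(json.loads(Path(path).read_text()))


def write_models(path, models: Mapping[str, LinearDiscriminantModel]) -> None:
    Path(path).write_text(
        json.dumps({k: m.to_dict() for k, m in models.items()}, indent=1)
    )


def read_model(path, name: str | None = None) -> LinearDiscriminantModel:
    """Read one model from a JSON file holding either a single model dict
    or a name -> model mapping (then ``name`` selects, defaulting to the
    sole entry)."""
    payload = json.loads(Path(path).read_text())
    if "weights" in payload:
        return LinearDiscriminantModel.from_dict(payload)
    if name is None:
        if len(payload) != 1:
            raise ValidationError(
                f"{path} holds {sorted(payload)}; specify which model to load"
            )
        name = next(iter(payload))
    if name not in payload:
        raise ValidationError(f"{path}: no model named {name!r}")
    return LinearDiscriminantModel.from_dict(payload[name])
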