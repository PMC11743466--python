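"""Reading and writing images, masks, ROI annotations and measurement tables.

Supported raster formats are single-channel 8- or 16-bit PNG and TIFF
(RGB inputs are converted by standard luminance weights).  ROI polygons
travel as JSON files holding a ``"polygon"`` list of ``[col, row]``
pairs.  Measurement tables are plain :class:`pandas.DataFrame` objects
written as CSV (UTF-8, ``.`` decimal) or JSON (records under a
``"records"`` key).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .datatypes import GlandMask, MeibographyImage, compact_labels, full_frame_roi, roi_to_mask
from .errors import InputError, ValidationError

logger = logging.getLogger(__name__)

_LUMA = np.array([0.2125, 0.7154, 0.0721])  # ITU-R 709, as used by scikit-image


def _read_raster(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # undecodable content
        raise InputError(f"could not decode {path}: {exc}") from exc
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        arr = arr[:, :, :3].astype(float) @ _LUMA
    return np.asarray(arr)


def load_image(
    path: str | Path,
    mm_per_px: float | None = None,
    eye_side: str = "unknown",
    eyelid: str = "upper",
    source_id: str | None = None,
) -> MeibographyImage:
    """Load a meibography frame with its calibration and laterality metadata.

    ``mm_per_px`` is mandatory configuration in spirit: when omitted it
    defaults to 1.0 and a warning notes that downstream lengths and areas
    are then in pixel units.
    """
    if mm_per_px is None:
        logger.warning(
            "no mm_per_px calibration given for %s: outputs will be in pixel units", path
        )
        mm_per_px = 1.0
    if mm_per_px <= 0:
        raise ValidationError(f"mm_per_px must be > 0, got {mm_per_px}")
    arr = _read_raster(path)
    intensity_max = 65535.0 if arr.dtype == np.uint16 else 255.0
    return MeibographyImage(
        pixels=arr.astype(np.float64),
        mm_per_px=float(mm_per_px),
        eye_side=eye_side,
        eyelid=eyelid,
        source_id=source_id if source_id is not None else Path(path).stem,
        intensity_max=intensity_max,
    )


def save_image(image: MeibographyImage, path: str | Path) -> None:
    """Write the raster as 8- or 16-bit PNG/TIFF depending on its range."""
    if image.intensity_max > 255:
        arr = np.clip(np.round(image.pixels), 0, 65535).astype(np.uint16)
    else:
        arr = np.clip(np.round(image.pixels), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), arr)


# ---------------------------------------------------------------------------
# masks and ROIs


def load_roi(path: str | Path) -> np.ndarray:
    """Read an ROI polygon from a JSON file with a ``"polygon"`` key."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such ROI file: {path}")
    payload = json.loads(path.read_text())
    poly = np.asarray(payload["polygon"], dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
        raise ValidationError("ROI polygon must be a list of >= 3 [col, row] pairs")
    return poly


def save_roi(roi: np.ndarray, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"polygon": np.asarray(roi, dtype=float).tolist()}, indent=1)
    )


def mask_from_array(
    raster: np.ndarray,
    roi: np.ndarray | str | None = "full-frame",
    mm_per_px: float = 1.0,
    source_id: str = "",
) -> GlandMask:
    """Build a validated GlandMask from a binary or labeled raster.

    Binary rasters (values {0, nonzero}) are split into 8-connected
    components; labeled rasters are compacted.  Components entirely
    outside the ROI are dropped with a logged warning.
    """
    raster = np.asarray(raster)
    if raster.size == 0 or raster.ndim != 2:
        raise ValidationError("mask raster must be 2-D and non-empty")
    values = np.unique(raster)
    structure = np.ones((3, 3), dtype=bool)
    if len(values) <= 2:  # binary (or empty)
        labels, _ = ndi.label(raster > 0, structure=structure)
    else:
        labels = raster.astype(np.int64)
    labels = compact_labels(labels)

    if roi is None or (isinstance(roi, str) and roi == "full-frame"):
        roi_poly = full_frame_roi(raster.shape)
    else:
        roi_poly = np.asarray(roi, dtype=float)
    inside = roi_to_mask(roi_poly, raster.shape)
    dropped = []
    for lab in range(1, int(labels.max()) + 1):
        sel = labels == lab
        if not np.any(sel & inside):
            labels[sel] = 0
            dropped.append(lab)
    if dropped:
        logger.warning("dropping %d component(s) entirely outside the ROI", len(dropped))
        labels = compact_labels(labels)
    mask = GlandMask(labels=labels, roi=roi_poly, mm_per_px=mm_per_px, source_id=source_id)
    mask.validate(check_roi=False)
    return mask


def load_mask(
    path: str | Path,
    roi: np.ndarray | str | None = "full-frame",
    mm_per_px: float = 1.0,
) -> GlandMask:
    """Load a gland mask raster (binary or labeled) from PNG/TIFF."""
    raster = _read_raster(path)
    return mask_from_array(
        raster, roi=roi, mm_per_px=mm_per_px, source_id=Path(path).stem
    )


def save_mask(mask: GlandMask, path: str | Path) -> None:
    """Write labels as a 16-bit PNG/TIFF (labels up to 65535)."""
    iio.imwrite(Path(path), mask.labels.astype(np.uint16))


# ---------------------------------------------------------------------------
# measurement tables


def write_measurements(table: pd.DataFrame, path: str | Path, format: str = "csv") -> None:
    """Write a measurement table as CSV or JSON.

    Round-tripping through :func:`read_measurements` reproduces numeric
    values to 1e-9 relative.
    """
    if table.shape[1] == 0:
        raise ValidationError("refusing to write a table with no columns")
    if table.columns.duplicated().any():
        raise ValidationError("column names must be unique")
    path = Path(path)
    if format == "csv":
        table.to_csv(path, index=False)
    elif format == "json":
        payload = {"records": json.loads(table.to_json(orient="records"))}
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValidationError(f"unknown format {format!r} (use 'csv' or 'json')")


def read_measurements(path: str | Path, format: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such table: {path}")
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        return pd.read_csv(path)
    payload = json.loads(path.read_text())
    return pd.DataFrame.from_records(payload["records"])
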