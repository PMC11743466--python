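"""Core raster containers: calibrated meibography images and gland masks.

Conventions used throughout the package:

* rasters are row-major ``numpy`` arrays, origin at the top-left, 0-based;
* ROI polygons are ``(N, 2)`` arrays of ``(col, row)`` vertices, closed
  implicitly (the last vertex connects back to the first);
* ``mm_per_px`` is an isotropic pixel pitch.  No device constant is
  assumed: when the caller does not know the calibration, ``1.0`` keeps
  all outputs in pixel units (a warning is logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from skimage.draw import polygon2mask
from scipy import ndimage as ndi

from .errors import ValidationError

logger = logging.getLogger(__name__)

EYE_SIDES = ("left", "right", "unknown")
EYELIDS = ("upper", "lower")


@dataclass
class MeibographyImage:
    """A single-channel infrared meibography frame with calibration.

    Parameters
    ----------
    pixels
        2-D grayscale raster, arbitrary intensity units, finite and
        non-negative.
    mm_per_px
        Millimetres per pixel (isotropic), strictly positive.
    eye_side, eyelid
        Laterality metadata; drives the nasal→temporal gland ordering.
    source_id
        Opaque identifier carried into every downstream table row.
    intensity_max
        Nominal full-scale intensity (255 for 8-bit input, 65535 for
        16-bit); augmentation clips to this range.
    """

    pixels: np.ndarray
    mm_per_px: float = 1.0
    eye_side: str = "unknown"
    eyelid: str = "upper"
    source_id: str = ""
    intensity_max: float = 255.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 2:
            raise ValidationError("pixels must be a 2-D raster with >= 2 rows and columns")
        if not np.all(np.isfinite(self.pixels)) or self.pixels.min() < 0:
            raise ValidationError("pixel intensities must be finite and non-negative")
        if not (np.isfinite(self.mm_per_px) and self.mm_per_px > 0):
            raise ValidationError(f"mm_per_px must be > 0, got {self.mm_per_px}")
        if self.eye_side not in EYE_SIDES:
            raise ValidationError(f"eye_side must be one of {EYE_SIDES}")
        if self.eyelid not in EYELIDS:
            raise ValidationError(f"eyelid must be one of {EYELIDS}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "MeibographyImage":
        """Copy of this image with a new raster, metadata unchanged."""
        return replace(self, pixels=np.asarray(pixels, dtype=np.float64))


def full_frame_roi(shape: tuple[int, int]) -> np.ndarray:
    """ROI polygon covering an entire ``(rows, cols)`` raster."""
    rows, cols = shape
    return np.array(
        [[-0.5, -0.5], [cols - 0.5, -0.5], [cols - 0.5, rows - 0.5], [-0.5, rows - 0.5]],
        dtype=float,
    )


def roi_to_mask(roi: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a ``(col, row)`` polygon into a boolean mask."""
    roi = np.asarray(roi, dtype=float)
    if roi.ndim != 2 or roi.shape[1] != 2 or roi.shape[0] < 3:
        raise ValidationError("roi must be an (N, 2) polygon with N >= 3 (col, row) vertices")
    # polygon2mask expects (row, col) vertex order
    return polygon2mask(shape, roi[:, ::-1])


@dataclass
class GlandMask:
    """Labeled gland raster plus the eyelid (tarsal) region of interest.

    ``labels`` uses 0 for background and 1..K for glands with a compact
    labeling (every value in 1..K present).  Each gland must be a single
    8-connected component lying inside ``roi``.
    """

    labels: np.ndarray
    roi: np.ndarray = None  # type: ignore[assignment]
    mm_per_px: float = 1.0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("labels must be an integer raster")
        if self.labels.ndim != 2 or self.labels.size == 0:
            raise ValidationError("labels must be a non-empty 2-D raster")
        if self.roi is None:
            self.roi = full_frame_roi(self.labels.shape)
        self.roi = np.asarray(self.roi, dtype=float)
        if not (np.isfinite(self.mm_per_px) and self.mm_per_px > 0):
            raise ValidationError(f"mm_per_px must be > 0, got {self.mm_per_px}")

    @property
    def n_glands(self) -> int:
        return int(self.labels.max())

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def gland(self, gland_id: int) -> np.ndarray:
        """Boolean mask of one gland."""
        if gland_id < 1 or gland_id > self.n_glands:
            raise ValidationError(f"gland_id {gland_id} not in 1..{self.n_glands}")
        return self.labels == gland_id

    def roi_mask(self) -> np.ndarray:
        return roi_to_mask(self.roi, self.labels.shape)

    def validate(self, check_roi: bool = True) -> None:
        """Check every invariant; raise ValidationError naming the rule."""
        labs = self.labels
        if labs.min() < 0:
            raise ValidationError("negative label values")
        present = np.unique(labs[labs > 0])
        k = self.n_glands
        if k and not np.array_equal(present, np.arange(1, k + 1)):
            raise ValidationError(
                f"labels are not compact: found {present.tolist()}, expected 1..{k}"
            )
        structure = np.ones((3, 3), dtype=bool)  # 8-connectivity
        for lab in present:
            _, n_comp = ndi.label(labs == lab, structure=structure)
            if n_comp != 1:
                raise ValidationError(
                    f"connectivity: label {lab} splits into {n_comp} 8-connected components"
                )
        if check_roi and k:
            inside = self.roi_mask()
            if np.any((labs > 0) & ~inside):
                bad = np.unique(labs[(labs > 0) & ~inside])
                raise ValidationError(
                    f"roi: labels {bad.tolist()} have pixels outside the ROI polygon"
                )


def compact_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel so values are exactly 0..K with K = number of glands.

    Order of first appearance of the old labels is preserved.
    """
    labels = np.asarray(labels)
    out = np.zeros_like(labels, dtype=np.int32)
    present = np.unique(labels[labels > 0])
    for new, old in enumerate(present, start=1):
        out[labels == old] = new
    return out
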