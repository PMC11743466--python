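"""Gland segmentation: a classical baseline plus a mask-ingestion slot.

The baseline is deliberately classical — local contrast equalization
inside the eyelid ROI, ridge enhancement tuned to quasi-vertical tubes,
Otsu thresholding, morphological cleanup — so that it runs without any
trained weights.  Masks produced by any external model (e.g. an
encoder-decoder segmentation network) enter through
:func:`ingest_external_mask`, which validates and compacts them; the
morphometry downstream is agnostic to where the mask came from.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure, filters, morphology
from skimage.measure import find_contours

from .datatypes import GlandMask, MeibographyImage, compact_labels, roi_to_mask
from .errors import ValidationError

logger = logging.getLogger(__name__)


def divide_regions(
    image: MeibographyImage, roi_override: np.ndarray | None = None
) -> np.ndarray:
    """Locate the eyelid tarsal region as a ``(col, row)`` polygon.

    With ``roi_override`` the polygon is returned verbatim.  Otherwise a
    coarse heuristic takes the convex hull of the largest bright region
    after Otsu thresholding of a smoothed copy of the frame.
    """
    if roi_override is not None:
        return np.asarray(roi_override, dtype=float)
    pixels = ndi.gaussian_filter(image.pixels, 3.0)
    if np.ptp(pixels) == 0:
        raise ValidationError(
            "image has no contrast: cannot locate the tarsal region, supply an ROI"
        )
    thresh = filters.threshold_otsu(pixels)
    bright = pixels > thresh
    if not bright.any():
        raise ValidationError("no pixel above threshold: supply an ROI polygon")
    labels, _ = ndi.label(bright, structure=np.ones((3, 3), bool))
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    hull = morphology.convex_hull_image(labels == largest)
    contour = max(find_contours(hull.astype(float), 0.5), key=len)
    contour = contour[:: max(len(contour) // 200, 1)]  # thin the polygon
    return contour[:, ::-1].copy()  # (row, col) -> (col, row)


def segment_baseline(
    image: MeibographyImage,
    roi: np.ndarray,
    min_area_mm2: float = 0.05,
) -> GlandMask:
    """Classical gland segmentation inside the ROI.

    Pipeline: Gaussian denoising and contrast rescaling over the ROI's
    intensity range → ridge filter (Sato tubeness over a small sigma
    range) → Otsu threshold of the ridge response inside the ROI, gated
    by an intensity Otsu so only bright tubes survive → morphological
    opening → removal of components smaller than ``min_area_mm2`` →
    compact labels.  May legitimately return zero glands.
    """
    inside = roi_to_mask(roi, image.shape)
    if not inside.any():
        raise ValidationError("ROI polygon covers no pixels")
    smooth = ndi.gaussian_filter(image.pixels, 1.0)
    vals = smooth[inside]
    if np.ptp(vals) == 0:
        labels = np.zeros(image.shape, dtype=np.int32)
        return GlandMask(labels=labels, roi=roi, mm_per_px=image.mm_per_px,
                         source_id=image.source_id)
    lo, hi = np.percentile(vals, [1, 99])
    eq = exposure.rescale_intensity(smooth, in_range=(lo, max(hi, lo + 1)))
    ridge = filters.sato(eq, sigmas=(1.5, 2.5, 3.5), black_ridges=False)
    # Otsu on a gland-free band just splits the noise; a robust noise floor
    # (median + 4 sigma via the MAD) keeps blank eyelids empty
    sigma_mad = 1.4826 * np.median(np.abs(vals - np.median(vals)))
    floor = np.median(vals) + 4.0 * sigma_mad
    bright = smooth > max(filters.threshold_otsu(vals), floor)
    ridge_vals = ridge[inside]
    if np.ptp(ridge_vals) > 0:
        binary = (ridge > filters.threshold_otsu(ridge_vals)) & bright & inside
    else:
        binary = bright & inside
    binary = morphology.opening(binary, morphology.disk(1))
    min_px = max(int(round(min_area_mm2 / image.mm_per_px**2)), 1)
    labels, _ = ndi.label(binary, structure=np.ones((3, 3), bool))
    sizes = np.bincount(labels.ravel())
    too_small = np.nonzero(sizes < min_px)[0]
    labels[np.isin(labels, too_small)] = 0
    mask = GlandMask(
        labels=compact_labels(labels),
        roi=roi,
        mm_per_px=image.mm_per_px,
        source_id=image.source_id,
    )
    return mask


def ingest_external_mask(mask: GlandMask) -> GlandMask:
    """Validate and compact a mask produced by an external segmentation model.

    Raises ValidationError naming the violated invariant (compactness,
    connectivity, ROI containment); returns a compacted copy otherwise.
    """
    compacted = GlandMask(
        labels=compact_labels(mask.labels),
        roi=mask.roi,
        mm_per_px=mask.mm_per_px,
        source_id=mask.source_id,
    )
    compacted.validate()
    return compacted
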