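import numpy as np
import pytest
from scipy.spatial import cKDTree

from meibomorph.datatypes import GlandMask


def rectangle_mask(length: int = 60, width: int = 6, mm_per_px: float = 1.0) -> GlandMask:
    """Axis-aligned horizontal rectangle gland, length x width pixels."""
    labels = np.zeros((width + 14, length + 20), dtype=np.int32)
    r0, c0 = 7, 10
    labels[r0 : r0 + width, c0 : c0 + length] = 1
    return GlandMask(labels, mm_per_px=mm_per_px)


def tube_mask(
    amplitude: float = 0.0,
    length: float = 90.0,
    width: float = 6.4,
    shape: tuple[int, int] = (130, 70),
    periods: float = 1.0,
    taper: float = 0.0,
    mm_per_px: float = 1.0,
) -> tuple[GlandMask, float]:
    """Capsule tube along a vertical sinusoid; returns (mask, true arc length px).

    The arc length includes the rounded caps (tip-to-tip extent along the
    centerline), matching what the measured centerline spans.
    """
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    y = np.linspace(12.0, 12.0 + length, 500)
    x = cols / 2 + amplitude * np.sin(2 * np.pi * periods * (y - 12.0) / length)
    poly = np.column_stack([y, x])
    tree = cKDTree(poly)
    dist, idx = tree.query(np.column_stack([yy.ravel(), xx.ravel()]))
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(poly, axis=0), axis=1))])
    half = (width / 2.0) * (1.0 - taper * arc[idx] / arc[-1])
    mask = (dist < half).reshape(rows, cols)
    true_arc = float(arc[-1]) + width / 2.0 + (width / 2.0) * (1.0 - taper)
    return GlandMask(mask.astype(np.int32), mm_per_px=mm_per_px), true_arc


@pytest.fixture(scope="session")
def rect60x6() -> GlandMask:
    return rectangle_mask(60, 6)


@pytest.fixture(scope="session")
def straight_tube():
    return tube_mask(amplitude=0.0)


@pytest.fixture(scope="session")
def curved_tube():
    return tube_mask(amplitude=9.0)
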