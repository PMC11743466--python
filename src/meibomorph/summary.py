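"""Per-eyelid aggregates: gland count, dropout ratio, means, central-five rule.

The clinically assessed region is the five central glands.  Given n
glands ordered nasal→temporal, the selection drops ``(n-5)/2`` glands
from each side when n is odd, and ``(n-6)/2`` nasal plus ``(n-4)/2``
temporal glands when n is even (one extra gland is dropped temporally).
With five or fewer glands everything is kept and a warning logged.

Gland dropout is quantified as the gland-free fraction of the tarsal
ROI: ``1 - (gland pixels inside the ROI) / (ROI pixels)``.  Absolute
values therefore depend on how tightly the ROI hugs the tarsal plate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GlandMask
from .errors import ValidationError
from .morphometry import GlandMorphometry

logger = logging.getLogger(__name__)


@dataclass
class EyelidSummary:
    """Per-image aggregates; missing aggregates are NaN, never zero."""

    source_id: str
    gland_count: int
    dropout_ratio: float
    avg_length_mm: float
    avg_width_mm: float
    avg_area_mm2: float
    avg_deformation: float
    central5_length_mm: float
    central5_width_mm: float
    central5_area_mm2: float
    central5_deformation: float
    central5_n: int

    def to_row(self) -> dict:
        return dict(self.__dict__)


def select_central5(glands: list) -> list:
    """The central five of a nasal→temporal ordered gland list.

    Implements the parity rule exactly: odd n drops ``(n-5)/2`` from both
    sides; even n drops ``(n-6)/2`` nasal and ``(n-4)/2`` temporal.  For
    n <= 5 all glands are returned with a logged warning.
    """
    n = len(glands)
    if n <= 5:
        if n < 5:
            logger.warning("only %d glands: central-5 selection returns all of them", n)
        return list(glands)
    if n % 2 == 1:
        drop_nasal = drop_temporal = (n - 5) // 2
    else:
        drop_nasal, drop_temporal = (n - 6) // 2, (n - 4) // 2
    return list(glands[drop_nasal : n - drop_temporal])


def dropout_ratio(mask: GlandMask) -> float:
    """Gland-free fraction of the ROI: ``1 - gland_area / roi_area``."""
    poly = np.asarray(mask.roi, dtype=float)
    x, y = poly[:, 0], poly[:, 1]
    shoelace = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if shoelace <= 0:
        raise ValidationError("degenerate ROI: zero polygon area")
    inside = mask.roi_mask()
    roi_px = int(inside.sum())
    if roi_px == 0:
        raise ValidationError("degenerate ROI: zero pixel area")
    gland_px = int(((mask.labels > 0) & inside).sum())
    return 1.0 - gland_px / roi_px


def _mean(values: list[float]) -> float:
    return float(np.mean(values)) if values else math.nan


def summarize_eyelid(glands: list[GlandMorphometry], mask: GlandMask) -> EyelidSummary:
    """Aggregate measured glands (nasal→temporal ordered) into one summary row."""
    measurable = [g for g in glands if not g.degenerate]
    central = select_central5(measurable)
    return EyelidSummary(
        source_id=mask.source_id,
        gland_count=len(measurable),
        dropout_ratio=dropout_ratio(mask),
        avg_length_mm=_mean([g.length_central_mm for g in measurable]),
        avg_width_mm=_mean([g.w_avg_mm for g in measurable]),
        avg_area_mm2=_mean([g.area_mm2 for g in measurable]),
        avg_deformation=_mean([g.deformation for g in measurable]),
        central5_length_mm=_mean([g.length_central_mm for g in central]),
        central5_width_mm=_mean([g.w_avg_mm for g in central]),
        central5_area_mm2=_mean([g.area_mm2 for g in central]),
        central5_deformation=_mean([g.deformation for g in central]),
        central5_n=len(central),
    )


def glands_to_table(glands: list[GlandMorphometry], source_id: str = "") -> pd.DataFrame:
    """One CSV-ready row per gland with every scalar morphometry field."""
    rows = []
    for g in glands:
        rows.append(
            {
                "source_id": source_id,
                "gland_id": g.gland_id,
                "length_central_mm": g.length_central_mm,
                "chord_mm": g.chord_mm,
                "p_a_mm": g.p_a_mm,
                "p_b_mm": g.p_b_mm,
                "w_avg_mm": g.w_avg_mm,
                "n_steps": g.n_steps,
                "area_mm2": g.area_mm2,
                "deformation": g.deformation,
                "tortuosity": g.tortuosity,
                "centroid_row": g.centroid_rc[0],
                "centroid_col": g.centroid_rc[1],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "source_id", "gland_id", "length_central_mm", "chord_mm", "p_a_mm",
            "p_b_mm", "w_avg_mm", "n_steps", "area_mm2", "deformation",
            "tortuosity", "centroid_row", "centroid_col",
        ],
    )
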