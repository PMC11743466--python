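"""Calibrated default scenarios: allergic-conjunctivitis-like and control-like.

The clinical margins (age, tear meniscus height, non-invasive TBUT,
conjunctival congestion, OSDI) and the reported meibomian-gland means
(overall length; central-five length and area) follow the published
group summaries for 252 allergic and 200 control eyes.  Margins that no
study reports numerically (gland count, dropout ratio, width,
deformation) use values a clinician would call typical for pediatric
meibography, and are flagged below.  Rank-correlation targets are the
eight pairs reported for the allergic group; the same structure is
applied to both groups.
"""

from __future__ import annotations

import numpy as np

from .synthetic import CohortSpec, EyelidSpec, Marginal

# Spearman rank-correlation targets (allergic-group report)
CORRELATION_TARGETS: list[tuple[str, str, float]] = [
    ("dropout_ratio", "sex", 0.19),
    ("dropout_ratio", "osdi", -0.24),
    ("dropout_ratio", "age_years", -0.19),
    ("gland_count", "nibut_first_s", -0.21),
    ("gland_count", "nibut_avg_s", -0.21),
    ("avg_area_mm2", "nibut_first_s", 0.17),
    ("avg_area_mm2", "nibut_avg_s", 0.17),
    ("congestion", "osdi", 0.19),
]

_M = Marginal  # shorthand

#: per-variable (allergy, control) margins; entries marked "assumed" are
#: not reported by the study and are plausible defaults.
COHORT_MARGINALS: dict[str, dict[str, Marginal]] = {
    "age_years": {"allergy": _M(11.78, 6.77, 5, 77), "control": _M(11.65, 9.0, 7, 58)},
    "tmh_mm": {"allergy": _M(0.26, 0.10, 0.05), "control": _M(0.44, 0.08, 0.05)},
    "nibut_first_s": {"allergy": _M(8.65, 6.31, 1.0), "control": _M(10.48, 2.58, 1.0)},
    "nibut_avg_s": {"allergy": _M(10.53, 6.26, 1.0), "control": _M(11.56, 3.67, 1.0)},
    "congestion": {"allergy": _M(1.1, 0.52, 0.0), "control": _M(0.97, 0.30, 0.0)},
    "osdi": {"allergy": _M(8.33, 7.6, 0.0, 100.0), "control": _M(4.00, 0.50, 0.0, 100.0)},
    # meibomian-gland summaries
    "gland_count": {"allergy": _M(24, 5, 6), "control": _M(22, 5, 6)},  # assumed
    "dropout_ratio": {"allergy": _M(0.35, 0.12, 0.0, 1.0), "control": _M(0.33, 0.12, 0.0, 1.0)},  # assumed
    "avg_length_mm": {"allergy": _M(4.48, 1.04, 0.5), "control": _M(4.72, 0.94, 0.5)},
    "avg_width_mm": {"allergy": _M(0.32, 0.06, 0.05), "control": _M(0.32, 0.06, 0.05)},  # assumed
    "avg_area_mm2": {"allergy": _M(1.45, 0.55, 0.1), "control": _M(1.55, 0.55, 0.1)},  # assumed
    "avg_deformation": {"allergy": _M(1.35, 0.25, 1.0), "control": _M(1.32, 0.25, 1.0)},  # assumed
    "central5_length_mm": {"allergy": _M(4.94, 1.67, 0.5), "control": _M(5.38, 1.42, 0.5)},
    "central5_width_mm": {"allergy": _M(0.33, 0.07, 0.05), "control": _M(0.33, 0.07, 0.05)},  # assumed
    "central5_area_mm2": {"allergy": _M(1.61, 0.64, 0.1), "control": _M(1.79, 0.62, 0.1)},
    "central5_deformation": {"allergy": _M(1.35, 0.25, 1.0), "control": _M(1.33, 0.25, 1.0)},  # assumed
}

SEX_RATIO = {"allergy": 153 / 252, "control": 121 / 200}
GROUP_SIZES = {"allergy": 252, "control": 200}


def cohort_spec(seed: int = 0, n_per_group: dict[str, int] | None = None) -> CohortSpec:
    """The default two-group cohort calibrated to the study summaries."""
    return CohortSpec(
        n_per_group=dict(n_per_group or GROUP_SIZES),
        marginals=COHORT_MARGINALS,
        sex_ratio=SEX_RATIO,
        correlations=list(CORRELATION_TARGETS),
        seed=seed,
    )


def ac_like_eyelid_spec(seed: int = 0, n_glands: int = 14, central5: bool = False) -> EyelidSpec:
    """An allergic-eyelid render spec with gland lengths from the AC group.

    With ``central5=True`` the gland length and width margins follow the
    central-five summaries instead (length 4.94 ± 1.67 mm; width chosen so
    the mean capsule area matches the central-five 1.61 mm^2).
    """
    taper = 0.1
    if central5:
        length_mean, length_sd = 4.94, 1.67
        area_target = 1.61

        def mean_area(w: float) -> float:
            # tip-to-tip capsule with linear taper: tapered body plus two
            # half-disk caps of the local tip radii
            h_top, h_bot = w / 2.0, w * (1.0 - taper) / 2.0
            body = (length_mean - h_top - h_bot) * w * (1.0 - taper / 2.0)
            return body + (np.pi / 2.0) * (h_top**2 + h_bot**2)

        from scipy.optimize import brentq

        width_mean = brentq(lambda w: mean_area(w) - area_target, 0.05, 1.2)
    else:
        length_mean, length_sd = 4.48, 1.04
        width_mean = 0.32
    return EyelidSpec(
        n_glands=n_glands,
        length_mean_mm=length_mean,
        length_sd_mm=length_sd,
        width_mean_mm=float(width_mean),
        width_sd_mm=0.04,
        curvature_amp=0.05,
        taper=taper,
        dropout_prob=0.0,
        image_size=(300, 560),
        mm_per_px=0.05,
        noise_sd=4.0,
        seed=seed,
    )


def control_like_eyelid_spec(seed: int = 0, n_glands: int = 14) -> EyelidSpec:
    """A control-eyelid render spec (length 4.72 ± 0.94 mm)."""
    spec = ac_like_eyelid_spec(seed=seed, n_glands=n_glands)
    spec.length_mean_mm, spec.length_sd_mm = 4.72, 0.94
    return spec
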