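"""Synthetic test beds: rendered eyelids with ground truth, and clinical cohorts.

Two generators emulate the study's data:

* :func:`generate_eyelid` renders an infrared-like frame — bright
  quasi-vertical gland tubes on a darker tarsal band — together with the
  ground-truth labeled mask and a per-gland truth table.  Gland
  centerlines are vertical sinusoids; lengths and widths are drawn from
  truncated normals; tubes get anti-aliased edges so downstream width
  measurement is exercised on realistic soft boundaries.  Dropout
  truncates or removes individual glands.

* :func:`generate_cohort` draws a per-eye clinical table through a
  Gaussian copula: a latent multivariate normal imposes target rank
  correlations, and each margin is transformed to a truncated normal
  whose parameters are moment-matched so the realized mean and SD hit the
  requested values despite the truncation.  Sex is derived from its own
  latent coordinate by thresholding at the requested male fraction, which
  preserves the sign of its correlations with the other variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial import cKDTree

from .datatypes import GlandMask, MeibographyImage
from .errors import SpacingError, ValidationError
import logging

logger = logging.getLogger(__name__)

# intensity model of the rendered frame (8-bit scale)
_BACKGROUND = 25.0
_BAND = 85.0
_TUBE = 175.0
_EDGE_SOFTNESS = 1.0  # px, anti-aliasing ramp of the tube profile


@dataclass
class EyelidSpec:
    """Parameters of one rendered eyelid."""

    n_glands: int = 12
    length_mean_mm: float = 4.5
    length_sd_mm: float = 1.0
    width_mean_mm: float = 0.32
    width_sd_mm: float = 0.05
    curvature_amp: float = 0.05  # lateral sinusoid amplitude, fraction of length
    taper: float = 0.0  # relative width loss from top to bottom
    dropout_prob: float = 0.0
    dropout_mode: str = "remove"  # or "truncate"
    truncate_frac: float = 0.4  # fraction of length kept when truncating
    image_size: tuple[int, int] = (300, 560)
    mm_per_px: float = 0.05
    noise_sd: float = 4.0  # Gaussian pixel noise on the image (not the mask)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_glands < 0:
            raise ValidationError("n_glands must be >= 0")
        if min(self.length_sd_mm, self.width_sd_mm) < 0:
            raise ValidationError("spread parameters must be >= 0")
        for p in (self.curvature_amp, self.taper, self.dropout_prob, self.truncate_frac):
            if not 0 <= p <= 1:
                raise ValidationError("curvature_amp, taper, dropout and truncate_frac lie in [0, 1]")
        if self.dropout_mode not in ("remove", "truncate"):
            raise ValidationError("dropout_mode must be 'remove' or 'truncate'")


_LENGTH_FLOOR_MM = 0.5  # truncated-normal lower bound for gland length


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lower: float, size: int
) -> np.ndarray:
    if sd == 0:
        return np.full(size, max(mean, lower))
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def _sinusoid_centerline(
    top_rc: tuple[float, float],
    arc_len_px: float,
    amp_px: float,
    phase: float,
    n_dense: int = 600,
) -> np.ndarray:
    """Vertical sinusoidal polyline with the requested arc length.

    The vertical extent is solved so that the polyline's arc length equals
    ``arc_len_px`` despite the lateral displacement.
    """
    r0, c0 = top_rc

    def _poly(height: float) -> np.ndarray:
        t = np.linspace(0.0, 1.0, n_dense)
        rows = r0 + t * height
        cols = c0 + amp_px * np.sin(2 * np.pi * t + phase) - amp_px * np.sin(phase)
        return np.column_stack([rows, cols])

    def _arc(height: float) -> float:
        p = _poly(height)
        return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())

    if amp_px == 0:
        return _poly(arc_len_px)
    height = optimize.brentq(
        lambda h: _arc(h) - arc_len_px, 0.2 * arc_len_px, arc_len_px + 1e-9, xtol=1e-3
    )
    return _poly(height)


def _resample_by_arc(poly: np.ndarray) -> np.ndarray:
    """Cumulative arc length of each polyline vertex."""
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def generate_eyelid(
    spec: EyelidSpec,
) -> tuple[MeibographyImage, GlandMask, pd.DataFrame]:
    """Render one eyelid: image, ground-truth mask and per-gland truth table.

    The truth table records, per surviving gland, the generated tip-to-tip
    centerline length (mm), mean width (mm), rendered pixel area (mm^2),
    curvature amplitude and whether dropout truncated it.  Deterministic
    given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.image_size
    px = spec.mm_per_px

    band_top, band_bottom = int(0.08 * rows), int(0.97 * rows)
    margin = max(int(0.03 * cols), 8)
    roi = np.array(
        [
            [margin - 4, band_top - 4],
            [cols - margin + 4, band_top - 4],
            [cols - margin + 4, band_bottom + 4],
            [margin - 4, band_bottom + 4],
        ],
        dtype=float,
    )

    image = np.full((rows, cols), _BACKGROUND)
    band_sel = np.zeros((rows, cols), dtype=bool)
    band_sel[band_top:band_bottom, margin : cols - margin] = True
    image[band_sel] = _BAND
    labels = np.zeros((rows, cols), dtype=np.int32)

    n = spec.n_glands
    lengths = _truncated_normal(rng, spec.length_mean_mm, spec.length_sd_mm, _LENGTH_FLOOR_MM, n)
    widths = _truncated_normal(rng, spec.width_mean_mm, spec.width_sd_mm, 0.08, n)
    phases = rng.uniform(0, 2 * np.pi, size=n)
    drop_draw = rng.random(n)
    truth_rows = []

    if n:
        spacing = (cols - 2.0 * margin) / n
    next_label = 1
    for i in range(n):
        length_mm, width_mm = float(lengths[i]), float(widths[i])
        dropped = drop_draw[i] < spec.dropout_prob
        if dropped and spec.dropout_mode == "remove":
            continue
        if dropped:
            length_mm = max(length_mm * spec.truncate_frac, _LENGTH_FLOOR_MM)

        w_px = width_mm / px
        length_px = length_mm / px
        amp_px = spec.curvature_amp * length_px
        col0 = margin + (i + 0.5) * spacing
        if length_px > (band_bottom - band_top) - 4:
            length_px = (band_bottom - band_top) - 4.0
            length_mm = length_px * px

        # capsule rendering: trim the centerline by the local cap radius at
        # both tips so the tip-to-tip extent of the tube equals length_mm
        poly = _sinusoid_centerline((band_top + 2.0, col0), length_px, amp_px, phases[i])
        arc = _resample_by_arc(poly)
        h_top = w_px / 2.0
        h_bot = w_px * (1.0 - spec.taper) / 2.0
        keep = (arc >= h_top) & (arc <= arc[-1] - h_bot)
        if keep.sum() < 2:
            continue  # too short to render at this width
        core_poly = poly[keep]
        core_arc = arc[keep]

        # local half-width along the core (linear taper over the full length)
        half_w = (w_px / 2.0) * (1.0 - spec.taper * core_arc / arc[-1])

        r_lo = max(int(core_poly[:, 0].min() - w_px - 3), 0)
        r_hi = min(int(core_poly[:, 0].max() + w_px + 4), rows)
        c_lo = max(int(core_poly[:, 1].min() - w_px - amp_px - 3), 0)
        c_hi = min(int(core_poly[:, 1].max() + w_px + amp_px + 4), cols)
        yy, xx = np.mgrid[r_lo:r_hi, c_lo:c_hi]
        pts = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
        tree = cKDTree(core_poly)
        dist, idx = tree.query(pts)
        local_half = half_w[idx]
        profile = np.clip((local_half - dist) / _EDGE_SOFTNESS + 0.5, 0.0, 1.0)
        profile = profile.reshape(yy.shape)
        tube_mask = profile > 0.5

        window = labels[r_lo:r_hi, c_lo:c_hi]
        if np.any(window[tube_mask] > 0):
            raise SpacingError(
                f"gland {i + 1} overlaps a neighbour: reduce n_glands, widths or curvature"
            )
        window[tube_mask] = next_label
        img_window = image[r_lo:r_hi, c_lo:c_hi]
        image[r_lo:r_hi, c_lo:c_hi] = np.maximum(
            img_window, _BAND + (_TUBE - _BAND) * profile
        )

        truth_rows.append(
            {
                "gland_id": next_label,
                "length_mm": length_mm,
                "width_mean_mm": width_mm * (1.0 - spec.taper / 2.0),
                "area_mm2": float(tube_mask.sum()) * px**2,
                "curvature_amp": spec.curvature_amp,
                "truncated": bool(dropped and spec.dropout_mode == "truncate"),
            }
        )
        next_label += 1

    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 255.0)

    source = f"synthetic-eyelid-seed{spec.seed}"
    mimage = MeibographyImage(
        pixels=image, mm_per_px=px, eye_side="right", eyelid="upper", source_id=source
    )
    mask = GlandMask(labels=labels, roi=roi, mm_per_px=px, source_id=source)
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "gland_id",
            "length_mm",
            "width_mean_mm",
            "area_mm2",
            "curvature_amp",
            "truncated",
        ],
    )
    truth.insert(0, "source_id", source)
    return mimage, mask, truth


# ---------------------------------------------------------------------------
# cohort generator


@dataclass
class Marginal:
    """Truncated-normal margin: target mean/SD after truncation to [lower, upper]."""

    mean: float
    sd: float
    lower: float = -np.inf
    upper: float = np.inf


@dataclass
class CohortSpec:
    """Calibration of a two-group synthetic clinical cohort.

    ``marginals`` maps variable name → {group name → Marginal}; ``sex_ratio``
    gives the male fraction per group; ``correlations`` lists target
    Spearman rank correlations as ``(var_i, var_j, rho)`` (unlisted pairs
    default to 0, with a nearest-PSD repair of the completed matrix).
    """

    n_per_group: dict[str, int]
    marginals: dict[str, dict[str, Marginal]]
    sex_ratio: dict[str, float]
    correlations: list[tuple[str, str, float]] = field(default_factory=list)
    integer_vars: tuple[str, ...] = ("gland_count",)
    seed: int = 0

    def __post_init__(self) -> None:
        for var, groups in self.marginals.items():
            for g, m in groups.items():
                if m.sd < 0:
                    raise ValidationError(f"negative sd for {var}/{g}")
        for a, b, rho in self.correlations:
            if not -1 <= rho <= 1:
                raise ValidationError(f"correlation target out of range: {(a, b, rho)}")


def _match_truncnorm(m: Marginal) -> tuple[float, float]:
    """Latent (mu, sigma) whose truncation to [lower, upper] has the target moments."""
    if m.sd == 0:
        return m.mean, 0.0
    lo, hi = m.lower, m.upper
    if not np.isfinite(lo) and not np.isfinite(hi):
        return m.mean, m.sd
    # mild truncation: latent == target to excellent approximation
    if (not np.isfinite(hi) or (hi - m.mean) / m.sd > 5) and (
        not np.isfinite(lo) or (m.mean - lo) / m.sd > 5
    ):
        return m.mean, m.sd

    # A one-sided truncated normal cannot have a coefficient of variation
    # (about the bound) above 1: as the latent mean recedes the shape tends
    # to an exponential with sd == mean - bound.  Requested spreads at or
    # beyond that supremum are clamped to a numerically attainable value.
    sd_target = m.sd
    if np.isfinite(lo) and m.mean > lo:
        sd_target = min(sd_target, 0.93 * (m.mean - lo))
    if np.isfinite(hi) and m.mean < hi:
        sd_target = min(sd_target, 0.93 * (hi - m.mean))
    if sd_target < m.sd:
        logger.warning(
            "marginal sd %.4g unattainable under truncation to [%g, %g] at mean %.4g; "
            "using %.4g", m.sd, lo, hi, m.mean, sd_target,
        )
    m = Marginal(m.mean, sd_target, lo, hi)

    def moments(params: np.ndarray) -> np.ndarray:
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        mean, var = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return np.array([mean - m.mean, np.sqrt(var) - m.sd])

    sol = optimize.root(moments, x0=np.array([m.mean, np.log(m.sd)]), method="hybr")
    if not sol.success:
        raise ValidationError(
            f"could not moment-match truncated normal for {m}: {sol.message}"
        )
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _nearest_psd_correlation(corr: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped, diagonal-renormalized PSD repair of a correlation matrix."""
    sym = 0.5 * (corr + corr.T)
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= eps:
        return sym
    vals = np.clip(vals, eps, None)
    repaired = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw the cohort table: one row per eye, deterministic given ``spec.seed``.

    Columns: ``eye_id``, ``group``, ``sex`` plus every variable in
    ``spec.marginals``.
    """
    rng = np.random.default_rng(spec.seed)
    variables = list(spec.marginals)
    names = variables + ["sex"]
    k = len(names)
    pos = {v: i for i, v in enumerate(names)}

    latent = np.eye(k)
    for a, b, rho in spec.correlations:
        if a not in pos or b not in pos:
            raise ValidationError(f"correlation names unknown: {(a, b)}")
        r = 2.0 * np.sin(np.pi * rho / 6.0)  # Spearman -> latent Pearson
        latent[pos[a], pos[b]] = latent[pos[b], pos[a]] = r
    latent = _nearest_psd_correlation(latent)
    chol = np.linalg.cholesky(latent)

    frames = []
    for group, n in spec.n_per_group.items():
        z = rng.standard_normal((n, k)) @ chol.T
        u = stats.norm.cdf(z)
        data: dict[str, np.ndarray] = {}
        for var in variables:
            marg = spec.marginals[var][group]
            mu, sigma = _match_truncnorm(marg)
            if sigma == 0:
                x = np.full(n, mu)
            else:
                a, b = (marg.lower - mu) / sigma, (marg.upper - mu) / sigma
                x = stats.truncnorm.ppf(u[:, pos[var]], a, b, loc=mu, scale=sigma)
            if var in spec.integer_vars:
                x = np.round(x)
            data[var] = x
        male_frac = spec.sex_ratio[group]
        sex = np.where(u[:, pos["sex"]] > 1.0 - male_frac, "male", "female")
        frame = pd.DataFrame(data)
        frame.insert(0, "sex", sex)
        frame.insert(0, "group", group)
        frame.insert(0, "eye_id", [f"{group}-{i:04d}" for i in range(n)])
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
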