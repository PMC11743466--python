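"""RandAugment-style augmentation policy for meibography frames.

A policy draws ``n_ops`` distinct operation types from a pool and pairs
each with an integer magnitude ``M`` drawn uniformly from
``[m_lo, m_hi] ⊆ [0, 10]``.  The magnitude is dimensionless; each
operation maps it onto its own physical scale:

==============  =============================================
op              magnitude schedule
==============  =============================================
rotate          angle = 3·M degrees (max 30°)
translate       shift = 1.5·M % of each dimension
shear           shear factor = 0.03·M
crop            retain (100 − 2·M)% central window, resize back
brightness      gain 1 ± 0.05·M (sign from the rng)
contrast        contrast factor 1 ± 0.05·M about the mean
equalize        histogram equalization (M ignored)
flip            horizontal mirror (M ignored)
==============  =============================================

All geometric operations preserve the raster dimensions (bilinear
interpolation, reflected borders) and ``M = 0`` is a near-identity.
Outputs are clipped to the image's nominal bit range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure
from skimage.transform import AffineTransform, resize, rotate as sk_rotate, warp

from .datatypes import MeibographyImage
from .errors import ValidationError

OP_POOL = (
    "crop",
    "flip",
    "shear",
    "translate",
    "rotate",
    "equalize",
    "contrast",
    "brightness",
)


@dataclass
class AugmentationPolicy:
    """Configuration of the random augmentation module (N ops, magnitude M)."""

    n_ops: int = 2
    magnitude_range: tuple[int, int] = (1, 10)
    op_pool: tuple[str, ...] = OP_POOL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ops < 0 or self.n_ops > len(self.op_pool):
            raise ValidationError(
                f"n_ops must be in 0..{len(self.op_pool)}, got {self.n_ops}"
            )
        m_lo, m_hi = self.magnitude_range
        if not (0 <= m_lo <= m_hi <= 10):
            raise ValidationError(
                f"magnitude_range must satisfy 0 <= lo <= hi <= 10, got {self.magnitude_range}"
            )
        unknown = set(self.op_pool) - set(OP_POOL)
        if unknown:
            raise ValidationError(f"unknown ops in pool: {sorted(unknown)}")


def sample_policy(
    policy: AugmentationPolicy, rng_state: int | None = None
) -> list[tuple[str, int]]:
    """Draw a concrete plan: ``n_ops`` distinct ops with random magnitudes.

    Deterministic given ``rng_state`` (defaults to the policy's seed).
    """
    seed = policy.seed if rng_state is None else rng_state
    rng = np.random.default_rng(seed)
    ops = rng.choice(len(policy.op_pool), size=policy.n_ops, replace=False)
    m_lo, m_hi = policy.magnitude_range
    mags = rng.integers(m_lo, m_hi + 1, size=policy.n_ops)
    return [(policy.op_pool[i], int(m)) for i, m in zip(ops, mags)]


def _apply_geometric(pixels: np.ndarray, op: str, m: int) -> np.ndarray:
    rows, cols = pixels.shape
    if op == "rotate":
        return sk_rotate(pixels, angle=3.0 * m, order=1, mode="reflect", preserve_range=True)
    if op == "translate":
        shift = (0.015 * m * cols, 0.015 * m * rows)
        tf = AffineTransform(translation=shift)
        return warp(pixels, tf.inverse, order=1, mode="reflect", preserve_range=True)
    if op == "shear":
        tf = AffineTransform(shear=0.03 * m)
        return warp(pixels, tf.inverse, order=1, mode="reflect", preserve_range=True)
    if op == "crop":
        keep = 1.0 - 0.02 * m
        dr = int(round(rows * (1 - keep) / 2))
        dc = int(round(cols * (1 - keep) / 2))
        window = pixels[dr : rows - dr or None, dc : cols - dc or None]
        return resize(window, (rows, cols), order=1, preserve_range=True, anti_aliasing=False)
    raise AssertionError(op)


def apply_augmentation(
    image: MeibographyImage,
    plan: list[tuple[str, int]],
    rng_state: int = 0,
) -> MeibographyImage:
    """Apply a sampled plan to an image; dimensions are preserved.

    ``rng_state`` feeds only the sign coin-flips of the brightness and
    contrast gains, so the call is deterministic given ``(plan, rng_state)``.
    An empty plan returns a pixel-identical copy.
    """
    rng = np.random.default_rng(rng_state)
    pixels = image.pixels.copy()
    vmax = image.intensity_max
    for op, m in plan:
        if op not in OP_POOL:
            raise ValidationError(f"unknown augmentation op {op!r}")
        if not 0 <= m <= 10:
            raise ValidationError(f"magnitude must be in [0, 10], got {m}")
        if op in ("rotate", "translate", "shear", "crop"):
            pixels = _apply_geometric(pixels, op, m)
        elif op == "flip":
            pixels = pixels[:, ::-1]
        elif op == "equalize":
            pixels = exposure.equalize_hist(pixels) * vmax
        elif op == "brightness":
            sign = 1.0 if rng.random() < 0.5 else -1.0
            pixels = pixels * (1.0 + sign * 0.05 * m)
        elif op == "contrast":
            sign = 1.0 if rng.random() < 0.5 else -1.0
            mean = pixels.mean()
            pixels = mean + (pixels - mean) * (1.0 + sign * 0.05 * m)
        pixels = np.clip(pixels, 0.0, vmax)
    return image.with_pixels(pixels)


def augment(
    image: MeibographyImage, policy: AugmentationPolicy, rng_state: int | None = None
) -> MeibographyImage:
    """Sample a plan from the policy and apply it (fully deterministic)."""
    seed = policy.seed if rng_state is None else rng_state
    plan = sample_policy(policy, seed)
    return apply_augmentation(image, plan, rng_state=seed)
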