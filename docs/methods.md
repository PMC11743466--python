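# Methods

## Measurement model

A gland in a meibography mask is treated as an unbranched tube.  All
geometry is computed in pixel space and scaled by the isotropic
calibration `mm_per_px` (mandatory configuration; with no calibration the
package uses 1.0 and warns that outputs are in pixel units — no device
constant is assumed).

**Centerline.**  The gland's morphological skeleton (Zhang thinning) is
reduced to its longest geodesic path via a double Dijkstra sweep on the
8-connected skeleton graph (exact on trees; glands are modeled
unbranched, so side branches are pruned).  Two numerical corrections
matter:

* the pixel chain is smoothed with a 7-point moving average — raw
  8-connected paths carry staircase noise that inflates curved arc
  lengths by ~3%;
* the path is extrapolated from both tips to the gland boundary along
  terminal tangents (total-least-squares line fits over a 12-point
  neighborhood, skipping the 3 jog-prone points at the tip).  Skeletons
  retract from tube caps by about half the local width; without the
  extension, length is biased low by roughly one gland width.

The path is ordered topmost point first (the lid-margin end).
`length_central` is the arc length of the extended path; `chord` the
straight distance between its tips; `tortuosity = length/chord`.

**Medial core.**  Widths and boundary arcs use only the *core* of the
centerline: points whose arc distance from both tips exceeds the local
radius (the Euclidean distance transform, EDT).  Inside the core the
centerline is genuinely medial; the excluded cap regions would otherwise
contaminate width samples and side-arc lengths.

**Width profile.**  At every `step_px`-th core point (default 1), width
is `2·EDT` converted to mm, with two further samples trimmed at each
end.  A half-pixel "−1" correction was considered and rejected: measured
against generator ground truth it under-reads anti-aliased oblique
tubes, while plain `2·EDT` is unbiased to ~1% on sinusoidal tubes (the
estimator's parity error on perfectly axis-aligned strips averages out
over realistic orientations).

**Boundary arcs `p_a`, `p_b`.**  The sub-pixel outer contour
(`find_contours` at 0.5) is cut by the planes perpendicular to the
centerline at the two core endpoints; contour segments straddling a
plane are clipped at it exactly.  Remaining segments are assigned left
or right of the oriented centerline by the sign of the local cross
product; `p_a` is the image-left side for a top-to-bottom path, and the
two swap under mirror reflection.  For a straight tube each side then
equals the core chord to a few parts in 10⁴.

**Deformation coefficient.**  Built on the arc–string-ratio model:

    D = (p_a · p_b / chord_core²) · (1 + s / w_avg),
    s = sqrt( Σ_{i=1..n} (w_i − w_avg)² / (n + 1) )

Both factors are ≥ 1 for tube geometry, D is dimensionless, and a
straight gland of uniform width scores exactly 1.  Numerical choices:
the string in the denominator is the chord of the *core* (the same span
the side arcs cover), so caps cancel; and the arc factor is floored at
its geometric minimum of 1, because digitization can push measured side
arcs fractionally below the chord on perfectly straight glands.  A
`variant="literal"` switch evaluates the bare product
`(p_a·p_b/chord²)·Σ(wᵢ−w_avg)²/(n+1)` for comparison; it is zero for
uniform widths and carries units, which is why the arc-string form is
the default.

**Degenerate glands** (fewer than 10 px, skeletons under 4 points, cores
too short for ≥ 2 width samples, zero chords) raise a dedicated error;
`measure_all` logs and skips them so one bad gland never aborts an
eyelid.

**Gland ordering and laterality.**  Records are ordered nasal→temporal
by centroid column: ascending for a right eye (nasal = image-left under
conventional acquisition), descending for a left eye, ascending with a
warning when the side is unknown.

## Eyelid summaries

Gland dropout is the gland-free fraction of the tarsal ROI,
`1 − gland_px/roi_px`; absolute values therefore depend on how tightly
the ROI hugs the tarsal plate, which is documented rather than hidden.
The central-five rule follows the printed parity arithmetic exactly,
including the asymmetric even-n split (the extra gland is dropped
temporally).  Aggregates over empty sets are NaN, never 0, so missing
eyelids cannot bias cohort statistics.

## Baseline segmentation

The shipped segmenter is classical by design — no trained weights are
distributed, and the mask-ingestion path (`ingest_external_mask`) lets
any learned model replace it without touching the morphometry.
Pipeline: Gaussian smoothing (σ=1) → percentile contrast rescaling over
the ROI → Sato tubeness (σ ∈ {1.5, 2.5, 3.5}) → Otsu threshold of the
ridge response gated by an intensity Otsu → a robust noise floor
(median + 4·MAD-σ) that keeps gland-free eyelids empty → opening →
minimum-area filter (default 0.05 mm²).  On synthetic renders this
recovers exact gland counts with Dice ≈ 0.96 up to noise σ = 12 (8-bit
scale).  Touching glands are not split (no watershed); that is a known
limitation.

## Augmentation

A policy draws `n_ops` distinct operation types (sampling without
replacement — "N types" implies distinct) and pairs each with an integer
magnitude M ∈ [m_lo, m_hi] ⊆ [0, 10].  The magnitude schedules are a
declared convention (the dimensionless M must map to physical scales
somehow): rotate 3M degrees, translate 1.5M% of each dimension, shear
0.03M, crop to the central (100−2M)% then resize back, brightness and
contrast gain 1 ± 0.05M with the sign drawn from the seeded rng;
equalize and horizontal flip ignore M.  Geometric operations use
bilinear interpolation with reflected borders (no black corners that
would corrupt intensity statistics), always return the input dimensions,
and M = 0 is a near-identity.  Everything is deterministic given
(policy, seed).

## Synthetic eyelids

Glands are capsules along vertical sinusoidal centerlines at uniform
horizontal spacing in a bright tarsal band (band 85, tubes 175,
background 25 on an 8-bit scale).  Lengths and widths are truncated
normal draws (length floor 0.5 mm); the sinusoid's vertical extent is
solved (Brent) so its *arc length* equals the drawn length, and the
rendered capsule is trimmed at the tips so its tip-to-tip extent equals
the draw — the truth table's `length_mm` is therefore exactly what the
centerline measurement should recover.  Tube edges get a 1 px
anti-aliasing ramp so width estimation faces realistic soft boundaries;
Gaussian pixel noise goes on the image only, never the mask.  Dropout
removes or truncates glands per a Bernoulli draw.  Overlapping layouts
raise an explicit spacing error.

What the renders do *not* emulate: intensity inhomogeneity and specular
reflections, gland branching and touching, partial eversion, motion
blur.  Passing recovery tests on these renders validates the geometry of
the measurement stack, not robustness to real-world image artifacts.

Default calibrated scenarios (`scenarios.py`) set the length margin to
the allergic group (4.48 ± 1.04 mm) or its central-five variant
(4.94 ± 1.67 mm with the width solved so the mean capsule area is
1.61 mm²); width 0.32 mm, curvature amplitude 0.05, taper 0.1, noise
σ=4 at 0.05 mm/px — values chosen once as clinically plausible.

## Synthetic cohorts

A Gaussian copula draws one latent multivariate normal per eye: target
Spearman correlations ρ are mapped to latent Pearson values via
`2·sin(πρ/6)`, the completed matrix is repaired to the nearest positive
semi-definite correlation matrix (eigenvalue clipping + diagonal
renormalization), and each margin is transformed to a truncated normal.
The truncation parameters are *moment-matched* (2-D root solve on the
truncated mean/SD) so realized moments hit the requested values — naive
truncation would bias bounded margins like OSDI upward.  Two margins are
special:

* a one-sided truncated normal cannot have SD ≥ (mean − bound) (the
  exponential limit); the reported age margins (11.78 ± 6.77 on [5, 77];
  11.65 ± 9 on [7, 58]) sit beyond that supremum, so the generator clamps
  the matchable SD to 0.93·(mean − bound) with a warning.  Means still
  match; the age spread is the one margin the truncated-normal family
  cannot reproduce.
* sex is thresholded from its own latent coordinate at the group's male
  fraction, which preserves correlation signs but attenuates magnitudes
  (biserial effect) — the sex–dropout recovery is therefore looser than
  the continuous pairs.

The eight reported rank correlations are imposed on both groups
(the source study reports them for the allergic group only); unlisted
pairs default to 0 before PSD repair.  Eyes are independent draws — no
within-patient clustering, matching how the cohort sizes are reported;
that is a statistical simplification, not a claim about real eyes.

## Statistics layer

Continuous comparisons are gated by per-group Shapiro-Wilk at α = 0.05:
both normal → two-sample t (Welch when a two-sided F variance-ratio test
rejects at 0.05), otherwise Mann-Whitney U.  Categorical variables use
chi-square, or Fisher's exact for 2×2 tables with any expected cell
< 5.  All tests are two-sided; no multiple-testing correction is applied
by default (a Benjamini-Hochberg helper exists).  Summary-statistic
t-tests reproduce printed-table comparisons; the pooled variant is the
default for that purpose.  Correlation matrices default to Spearman
(robust for ordinal congestion/OSDI scales), with sex encoded
female = 0 / male = 1 so positive coefficients read "higher in males".
`power_sample_size` searches integers over the exact noncentral-t power
function; the null rejection rate of the gated comparison is verified at
5% ± 2% by simulation.

## Problem sizes and determinism

The recovery experiments use 18 rendered eyelids × 14 glands = 252
glands (matching the allergic-group eye count) and copula cohorts of
252 + 200 eyes; these sizes make the mean-recovery sampling error
(~σ/√252 ≈ 1.5% for length) comfortably smaller than the 5% acceptance
bands.  Every stochastic component takes an explicit integer seed and is
bit-reproducible; batch seeds are derived from a single master seed via
`numpy.random.default_rng`.

## Known limitations

* No gland splitting for touching glands; no branching topology.
* The deformation floor relies on the arc-factor clamp; strongly curved
  *and* very wide glands can have a true arc–string factor below 1,
  which the clamp hides by design.
* Dropout depends on ROI tightness; cross-study comparisons need a
  consistent ROI protocol.
* The truncated-normal margin family cannot reproduce the reported age
  spread (see above) and real clinical variables may be skewed in ways
  mean ± SD does not capture.
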