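# meibomorph

Quantitative morphometry for infrared meibography — the imaging of
meibomian glands on the everted eyelid.  Meibomian glands secrete the
lipid layer that stabilizes the tear film; conditions such as allergic
conjunctivitis remodel them (shorter glands, central atrophy, dropout),
and grading those changes by eye is subjective and poorly reproducible.
`meibomorph` gives researchers a reproducible measurement stack: per-gland
geometry from a segmentation mask, eyelid-level summaries, calibrated
synthetic test beds, and the statistics layer for two-group clinical
cohorts.

## What it computes

For each gland (a bright quasi-vertical tube in the mask) the package
extracts a centerline (skeleton → longest geodesic path → extension to
the gland tips) and derives:

* **length (central)** — centerline arc length, mm;
* **width profile** `w_1..w_n` — twice the Euclidean distance transform
  sampled along the medial core, mm;
* **boundary arc lengths** `p_a`, `p_b` — left/right gland contours
  between perpendicular cuts at the core endpoints;
* **deformation coefficient**, built on the arc–string (arc–chord) ratio:

  `D = (p_a · p_b / chord²) · (1 + s / w_avg)`,  `s = √( Σᵢ (wᵢ − w_avg)² / (n+1) )`

  dimensionless, with minimum 1: a straight gland of uniform width scores
  exactly 1, and curvature or width variability raises it;
* **tortuosity** — arc length / chord; **area**, mm².

Per eyelid it aggregates gland count, gland dropout ratio (gland-free
fraction of the tarsal ROI), means of all parameters, and the
**central-five** aggregates: with n glands ordered nasal→temporal, the
selection drops `(n−5)/2` per side for odd n, and `(n−6)/2` nasal plus
`(n−4)/2` temporal for even n.

Around the measurements sit: a RandAugment-style augmentation policy
(N random ops with magnitude M ∈ [1,10]), a classical baseline segmenter
(any external segmentation model can supply masks instead), synthetic
eyelid and Gaussian-copula cohort generators with ground truth, and the
statistics layer (normality-gated t / Mann-Whitney / chi-square / Fisher
comparisons, Spearman correlation matrices, noncentral-t power analysis).

## Worked example

`examples/01_render_and_measure.py` renders a 14-gland synthetic eyelid
calibrated to an allergic-group length distribution (4.48 ± 1.04 mm),
measures it, and prints measurement vs generator truth:

```
gland   len mm   true  width   area  deform   tort
    1     4.73   4.81   0.30   1.45   1.218  1.027
    2     5.74   5.80   0.30   1.75   1.195  1.025
    ...
eyelid: 14 glands, dropout 0.95, mean length 4.37 mm (generated mean 4.44 mm),
central-5 area 1.39 mm^2
```

Measured lengths track the generated centerline lengths to ~1–2%;
deformation stays above its floor of 1 for these gently curved glands.
The other examples cover the deformation coefficient on closed-form
geometry (`02`), the augmentation policy (`03`), the cohort statistics
layer (`04` — e.g. tear meniscus height 0.26 ± 0.10 vs 0.44 ± 0.08 mm,
p ≈ 1e-56), and the power analysis (`05` — d = 0.5, α = 0.05, 80% power
→ 64 eyes per group).

A thin CLI wraps the same functions:

```bash
meibomorph simulate eyelid --seed 1 --out out/
meibomorph measure --mask out/mask.png --roi out/roi.json --mm-per-px 0.05 --out glands.csv
meibomorph cohort --table cohort.csv --compare tmh_mm --correlate --out report.json
```

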