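"""Render a synthetic eyelid and measure every gland.

Builds an allergic-conjunctivitis-like eyelid (14 glands whose lengths
follow a truncated normal, 4.48 +/- 1.04 mm), measures each gland from
the ground-truth mask, and prints the per-gland morphometry next to the
generator's truth so you can see the recovery quality directly.
"""

import numpy as np

from meibomorph import measure_all, scenarios, summarize_eyelid
from meibomorph.synthetic import generate_eyelid

spec = scenarios.ac_like_eyelid_spec(seed=7)
image, mask, truth = generate_eyelid(spec)
glands = measure_all(mask, eye_side="right")

print(f"{'gland':>5} {'len mm':>8} {'true':>6} {'width':>6} {'area':>6} {'deform':>7} {'tort':>6}")
truth_by_id = truth.set_index("gland_id")
for g in glands:
    t = truth_by_id.loc[g.gland_id]
    print(
        f"{g.gland_id:>5} {g.length_central_mm:8.2f} {t.length_mm:6.2f} "
        f"{g.w_avg_mm:6.2f} {g.area_mm2:6.2f} {g.deformation:7.3f} {g.tortuosity:6.3f}"
    )

summary = summarize_eyelid(glands, mask)
print(
    f"\neyelid: {summary.gland_count} glands, dropout {summary.dropout_ratio:.2f}, "
    f"mean length {summary.avg_length_mm:.2f} mm "
    f"(generated mean {truth.length_mm.mean():.2f} mm), "
    f"central-5 area {summary.central5_area_mm2:.2f} mm^2"
)
print(
    "Lengths are centerline arcs in mm; deformation is 1 for a straight uniform "
    "tube and grows with curvature or width variability."
)
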