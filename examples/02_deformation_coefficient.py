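"""The deformation coefficient on controlled geometry.

Evaluates D = (p_a * p_b / chord^2) * (1 + s / w_avg) on hand-built
inputs and on rendered glands: a straight uniform tube scores exactly 1,
an annular sector matches its closed form, and curvature or taper raises
the score.
"""

import numpy as np

from meibomorph import deformation_coefficient, measure_all, scenarios
from meibomorph.synthetic import generate_eyelid

# hand inputs: straight uniform gland
d = deformation_coefficient(60, 60, 60, np.full(10, 6.0))
print(f"straight uniform (p_a=p_b=chord, constant widths): D = {d:.6f}  (floor)")

# annular sector closed form: p_a=11*pi, p_b=9*pi, chord 20 -> 99*pi^2/400
d = deformation_coefficient(11 * np.pi, 9 * np.pi, 20.0, np.full(5, 2.0))
print(f"half-annulus R=10 w=2:                              D = {d:.4f}  (99*pi^2/400 = {99*np.pi**2/400:.4f})")

# rendered glands: straight vs curved vs tapered
for label, curv, taper in [("straight", 0.0, 0.0), ("curved", 0.15, 0.0), ("tapered", 0.0, 0.4)]:
    spec = scenarios.ac_like_eyelid_spec(seed=3, n_glands=8)
    spec.curvature_amp, spec.taper = curv, taper
    spec.width_sd_mm = spec.noise_sd = 0.0
    spec.length_sd_mm = 0.0
    _, mask, _ = generate_eyelid(spec)
    ds = [g.deformation for g in measure_all(mask, eye_side="right")]
    print(f"rendered {label:9s} glands: D in [{min(ds):.4f}, {max(ds):.4f}]")
print("Scores above 1 flag glands that bend or change width along their length.")
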