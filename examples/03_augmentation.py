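"""Sample and apply an augmentation policy (N random ops, magnitude M).

The default policy draws N=2 distinct operations with integer magnitudes
in [1, 10]; the same (policy, seed) always yields the bit-identical
augmented frame.
"""

import numpy as np

from meibomorph import AugmentationPolicy, augment, sample_policy, scenarios
from meibomorph.synthetic import generate_eyelid

image, _, _ = generate_eyelid(scenarios.ac_like_eyelid_spec(seed=4))
policy = AugmentationPolicy(n_ops=2, magnitude_range=(1, 10), seed=7)

plan = sample_policy(policy)
print("sampled plan:", plan)

out1 = augment(image, policy)
out2 = augment(image, policy)
print("deterministic:", np.array_equal(out1.pixels, out2.pixels))
print(
    f"intensity before {image.pixels.mean():.1f} -> after {out1.pixels.mean():.1f}; "
    f"dimensions {image.shape} -> {out1.shape} (always preserved)"
)
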