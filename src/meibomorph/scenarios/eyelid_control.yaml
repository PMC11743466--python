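n_glands: 14
length_mean_mm: 4.72
length_sd_mm: 0.94
width_mean_mm: 0.32
width_sd_mm: 0.04
curvature_amp: 0.05
taper: 0.1
dropout_prob: 0.0
dropout_mode: remove
truncate_frac: 0.4
image_size:
- 300
- 560
mm_per_px: 0.05
noise_sd: 4.0
seed: 0
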