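# Normal-shoulder cohort: ground-truth vault version 8.9 ± 2.7 deg; the
# body-shape offset 7.8 ± 1.718 deg reproduces a conventional version of
# 1.1 ± 3.2 deg (sd from the independent-Gaussian decomposition
# sqrt(3.2^2 - 2.7^2)).
description: normal shoulders, zero landmark noise
n_shoulders: 150
vault_version_mean_deg: 8.9
vault_version_sd_deg: 2.7
body_offset_mean_deg: 7.8
body_offset_sd_deg: 1.718
dominance_shift_deg: 0.0
paired: false
inclination_range_deg: [0.0, 30.0]
landmark_noise_sd_mm: 0.0
random_transform: true
glenoid_width_mm: 28.0
vault_depth_mm: 30.0
medial_border_mm: 100.0
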