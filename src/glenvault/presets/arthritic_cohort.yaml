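# Arthritic-shoulder cohort: ground-truth vault version 18.2 ± 9.1 deg;
# offset 7.4 ± 1.918 deg yields conventional version 10.8 ± 9.3 deg
# (sd from sqrt(9.3^2 - 9.1^2)).  All synthetic arthritic shoulders use the
# standard glenoid line (no per-morphology intermediate lines).
description: arthritic shoulders, zero landmark noise
n_shoulders: 150
vault_version_mean_deg: 18.2
vault_version_sd_deg: 9.1
body_offset_mean_deg: 7.4
body_offset_sd_deg: 1.918
dominance_shift_deg: 0.0
paired: false
inclination_range_deg: [0.0, 30.0]
landmark_noise_sd_mm: 0.0
random_transform: true
glenoid_width_mm: 28.0
vault_depth_mm: 30.0
medial_border_mm: 100.0
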