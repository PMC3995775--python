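# Paired dominance cohort (75 subjects, 150 shoulders): nondominant-side
# baseline vault version 8.2 ± 2.6 deg with a +1.4 deg shift on the dominant
# side (dominant 9.6 deg); offset 7.4 ± 1.688 deg gives nondominant
# conventional version 0.8 ± 3.1 deg (sd from sqrt(3.1^2 - 2.6^2)).
description: paired dominant/nondominant normal shoulders
n_shoulders: 150
vault_version_mean_deg: 8.2
vault_version_sd_deg: 2.6
body_offset_mean_deg: 7.4
body_offset_sd_deg: 1.688
dominance_shift_deg: 1.4
paired: true
inclination_range_deg: [0.0, 30.0]
landmark_noise_sd_mm: 0.0
random_transform: true
glenoid_width_mm: 28.0
vault_depth_mm: 30.0
medial_border_mm: 100.0
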