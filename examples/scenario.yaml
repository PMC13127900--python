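# One 30-minute synthetic session with three contractions and some motion.
n_frames: 120
grid_shape: [96, 96, 24]
voxel_size_mm: [2.4, 2.4, 6.0]
slice_spacing_mm: 10.0
te_ms: 25.0
tr_min_s: 9.0
tr_mean_s: 15.0
uterus_semiaxes_mm: [80, 70, 60]
wall_thickness_mm: 12.0
placenta_cap_angle_deg: 60.0
placenta_thickness_mm: 28.0
noise_sd_fraction: 0.02
events:
  - kind: placental
    onset_s: 200.0
    duration_s: 300.0
    amplitude: 0.20
    profile: tukey
    profile_params: {taper_fraction: 0.25}
  - kind: uterine_uniform
    onset_s: 800.0
    duration_s: 260.0
    amplitude: 0.15
    profile: tukey
    profile_params: {taper_fraction: 0.25}
  - kind: placental
    onset_s: 1300.0
    duration_s: 280.0
    amplitude: 0.25
    profile: raised_cosine
motion_events:
  - [30, maternal, 10.0]
  - [95, fetal, 1.0]
rng_seed: 7
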