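# Generator preset emulating the bundled vildagliptin 50 mg study:
# 5 sampling times, fast first-order release plateauing near 99 %,
# a slight post-peak decline, and the reference profile's per-time SDs.
# Test offsets span the same similar-but-distinct range as the six
# marketed generics (uniform plateau shifts of roughly +-0.5 to +4 %).
grid: [10, 15, 20, 30, 45]
reference_label: Ref
reference:
  f_inf: 99.0
  tau: 3.0
  beta: 1.0
  decay: 0.04
  noise_sd: [0.9, 0.94, 0.94, 0.91, 0.97]
  n_reps: 3
test_deltas:
  - {label: G-1, f_inf: 1.3, tau: -0.5}
  - {label: G-2, f_inf: 3.9}
  - {label: G-3, f_inf: 0.7}
  - {label: G-4, f_inf: -1.4}
  - {label: G-5, f_inf: -2.1}
  - {label: G-6, f_inf: 0.5}
method:
  medium: 0.01 N HCl
  volume_ml: 1000
  apparatus: USP 2 (paddle)
  speed_rpm: 50
  temp_c: 37
  detection: HPLC (210 nm)
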