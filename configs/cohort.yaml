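# Synthetic cohort comparison: 149 subjects, 39 intact / 75 partial /
# 35 full-thickness, measured for 3D volume and Y-view occupation ratio.
experiment: cohort
seed: 1
spacing_mm: [1.0, 3.3, 1.0]
reader_noise_sigma: 0.05
cohort:
  n_intact: 39
  n_partial: 75
  n_full: 35
  ellman_grade_counts: [45, 19, 11]
  patte_grade_counts: [19, 10, 6]
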