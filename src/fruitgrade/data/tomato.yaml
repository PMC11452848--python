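# Synthetic four-grade tomato population (not calibrated to real fruit).
# Grade 1 = ripest/largest; color, size and weight all fall with grade.
species: tomato
template:
  image_size: [120, 160]
  center: [60.0, 80.0]
  background_level: 235.0
  shadow_offset_px: 6
  shadow_darkening: 0.08
  noise_sd: 4.0
grades:
  - {grade_index: 1, color_mean: [200, 40, 35], color_sd: [4, 4, 4], radius_mean_px: 26.5, radius_sd_px: 0.6, weight_mean_g: 140, weight_sd_g: 4}
  - {grade_index: 2, color_mean: [180, 60, 40], color_sd: [4, 4, 4], radius_mean_px: 23.5, radius_sd_px: 0.6, weight_mean_g: 120, weight_sd_g: 4}
  - {grade_index: 3, color_mean: [160, 85, 45], color_sd: [4, 4, 4], radius_mean_px: 20.5, radius_sd_px: 0.6, weight_mean_g: 100, weight_sd_g: 4}
  - {grade_index: 4, color_mean: [130, 115, 50], color_sd: [4, 4, 4], radius_mean_px: 17.5, radius_sd_px: 0.6, weight_mean_g: 80, weight_sd_g: 4}
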