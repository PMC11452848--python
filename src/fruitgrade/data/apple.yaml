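# Synthetic four-grade red-apple population (not calibrated to real fruit).
# Apples are graded mainly on size and weight; color steps are smaller.
species: apple
template:
  image_size: [120, 160]
  center: [60.0, 80.0]
  background_level: 235.0
  shadow_offset_px: 6
  shadow_darkening: 0.08
  noise_sd: 4.0
grades:
  - {grade_index: 1, color_mean: [150, 30, 40], color_sd: [4, 4, 4], radius_mean_px: 30.5, radius_sd_px: 0.6, weight_mean_g: 200, weight_sd_g: 5}
  - {grade_index: 2, color_mean: [135, 45, 45], color_sd: [4, 4, 4], radius_mean_px: 27.5, radius_sd_px: 0.6, weight_mean_g: 170, weight_sd_g: 5}
  - {grade_index: 3, color_mean: [120, 60, 50], color_sd: [4, 4, 4], radius_mean_px: 24.5, radius_sd_px: 0.6, weight_mean_g: 140, weight_sd_g: 5}
  - {grade_index: 4, color_mean: [100, 80, 55], color_sd: [4, 4, 4], radius_mean_px: 21.5, radius_sd_px: 0.6, weight_mean_g: 110, weight_sd_g: 5}
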