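# Synthetic four-grade lemon population (not calibrated to real fruit).
# Lemons are light; grays stay safely below the 185 upper threshold so the
# default segmentation still separates fruit from the bright background.
species: lemon
template:
  image_size: [120, 160]
  center: [60.0, 80.0]
  background_level: 235.0
  shadow_offset_px: 6
  shadow_darkening: 0.08
  noise_sd: 4.0
grades:
  - {grade_index: 1, color_mean: [205, 170, 55], color_sd: [4, 4, 4], radius_mean_px: 22.5, radius_sd_px: 0.45, weight_mean_g: 110, weight_sd_g: 3}
  - {grade_index: 2, color_mean: [195, 160, 60], color_sd: [4, 4, 4], radius_mean_px: 20.5, radius_sd_px: 0.45, weight_mean_g: 95, weight_sd_g: 3}
  - {grade_index: 3, color_mean: [180, 145, 70], color_sd: [4, 4, 4], radius_mean_px: 18.5, radius_sd_px: 0.45, weight_mean_g: 80, weight_sd_g: 3}
  - {grade_index: 4, color_mean: [160, 130, 80], color_sd: [4, 4, 4], radius_mean_px: 16.5, radius_sd_px: 0.45, weight_mean_g: 65, weight_sd_g: 3}
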