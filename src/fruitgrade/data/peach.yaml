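# Synthetic four-grade peach population (not calibrated to real fruit).
# The default species: color, size and weight change together with grade.
species: peach
template:
  image_size: [120, 160]
  center: [60.0, 80.0]
  background_level: 235.0
  shadow_offset_px: 6
  shadow_darkening: 0.08
  noise_sd: 4.0
grades:
  - {grade_index: 1, color_mean: [235, 130, 90], color_sd: [4, 4, 4], radius_mean_px: 30.5, radius_sd_px: 0.6, weight_mean_g: 180, weight_sd_g: 5}
  - {grade_index: 2, color_mean: [215, 140, 95], color_sd: [4, 4, 4], radius_mean_px: 27.5, radius_sd_px: 0.6, weight_mean_g: 150, weight_sd_g: 5}
  - {grade_index: 3, color_mean: [195, 150, 100], color_sd: [4, 4, 4], radius_mean_px: 24.5, radius_sd_px: 0.6, weight_mean_g: 120, weight_sd_g: 5}
  - {grade_index: 4, color_mean: [170, 160, 105], color_sd: [4, 4, 4], radius_mean_px: 21.5, radius_sd_px: 0.6, weight_mean_g: 90, weight_sd_g: 5}
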