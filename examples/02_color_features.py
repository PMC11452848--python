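"""Measure a fruit's color the way the sorter does: sample 15 points inside
the fruit, average RGB, and convert to chromaticities and HSI."""

from fruitgrade import ColorSampleConfig, FruitSpec, extract_features, render_fruit_image

spec = FruitSpec(fruit_color=(220.0, 110.0, 70.0), axes=(26.3, 29.5), noise_sd=5.0)
image, mask = render_fruit_image(spec, rng_seed=3)

fv = extract_features(image, mask, weight_g=152.0, config=ColorSampleConfig(n_points=15, rng_seed=0))

print(f"mean RGB over 15 points: ({fv.R_mean:.1f}, {fv.G_mean:.1f}, {fv.B_mean:.1f})")
print(f"true fruit color:        (220.0, 110.0, 70.0)")
print(f"chromaticities r,g,b:    ({fv.r:.3f}, {fv.g:.3f}, {fv.b:.3f})  (sum to 1)")
print(f"hue H:                   {fv.H:.4f} of a turn (0 = red, 1/3 = green, 2/3 = blue)")
print(f"saturation S:            {fv.S:.3f} (0 = gray, 1 = pure color)")
print(f"intensity I:             {fv.I:.1f} of 255")
print(f"size: {fv.size_px} px, weight: {fv.weight_g} g")
# point averaging keeps the camera-noise error on each channel near
# noise_sd/sqrt(15), well under one gray level here
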