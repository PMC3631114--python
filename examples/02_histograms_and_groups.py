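"""Descriptor histograms and group summary tables.

Builds two small groups of slices (fatigued vs control) whose pore
populations differ in roughness, then prints the per-group descriptor
means and the area histogram (bin width 60 um^2).
"""

import bonepore as bp

slices = []
for treatment, roughness, seed0 in [("C", 0.0, 0), ("F", 0.25, 10)]:
    for k in range(3):
        spec = bp.SyntheticImageSpec(
            width_px=400, height_px=400, n_objects=12,
            axis_length_range_px=(12, 26), axis_ratio_range=(1, 2),
            roughness_amplitude=roughness, seed=seed0 + k,
        )
        image, _ = bp.generate_pore_image(spec)
        morpho = bp.measure_slice(bp.run_protocol(image))
        slices.append((morpho, "AM", treatment))

summary = bp.summarize_groups(slices)
cols = ["histology", "treatment", "n_slices", "n_objects",
        "shape_roughness_mean", "circularity_mean", "pore_fraction_mean"]
print(summary[cols].to_string(index=False))
# fatigued pores (roughened boundaries) show lower SR and higher C.

edges, counts, rel = slices[0][0].histograms["area_um2"]
print("\narea histogram of the first control slice (60 um^2 bins):")
for left, right, c, f in zip(edges[:-1], edges[1:], counts, rel):
    if c:
        print(f"  [{left:6.0f}, {right:6.0f})  n={c:2d}  rel={f:.3f}")
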