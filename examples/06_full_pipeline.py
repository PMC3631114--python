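"""End-to-end cohort run: images -> morphometry -> statistics -> manifest.

Builds a small 2x2 cohort (two histologies x fatigued/control, two
slices each), runs the whole pipeline and shows where the outputs live.
Outputs are written under ./bonepore_demo_out/.
"""

import bonepore as bp
from bonepore.pipeline import ImageInput

inputs = []
seed = 0
for hist, rough in [("AM", 0.05), ("PL", 0.2)]:
    for treat in ("F", "C"):
        for k in range(2):
            spec = bp.SyntheticImageSpec(
                width_px=384, height_px=384, n_objects=10,
                axis_length_range_px=(12, 24), axis_ratio_range=(1, 2),
                roughness_amplitude=rough if treat == "F" else 0.0,
                noise_fraction=0.02, seed=seed,
            )
            image, _ = bp.generate_pore_image(spec)
            inputs.append(ImageInput(image, hist, treat, name=f"{hist}_{treat}_{k}"))
            seed += 1

config = bp.PipelineConfig(output_dir="bonepore_demo_out")
manifest = bp.run_pipeline(config, inputs)

print(f"processed {len(manifest.inputs)} inputs, {manifest.n_failed} failures")
print("outputs:")
for out in manifest.outputs:
    print("  ", out["path"])
print("\nper-group object counts are in group_summary.csv; ANOVA p-values")
print("per descriptor (and pore fraction) are in anova.csv; the manifest")
print("records config, checksums and timings for reproducibility.")
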