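"""Rebuild a 3D tumor from simulated histology sections.

Cuts a phantom into ~4 mm coronal blocks with jittered spacing, places
each section on its slide with a random rotation/translation, registers
the sections back with a landmark-based similarity fit, stacks them at
the true spacings, and measures how well the stacked tumor matches the
original (volume error and 95th-percentile Hausdorff distance).
"""

import digispec as ds

phantom = ds.generate_phantom(
    ds.PhantomConfig(spacing_mm=0.8, tumor_center_mm=(1.0, 2.0, -2.0), seed=4)
)
vol = phantom.volume

stack = ds.simulate_sectioning(
    phantom, mean_thickness_mm=4.0, spacing_jitter_mm=1.5, shrink_healthy=0.95, seed=4
)
print(f"{len(stack)} sections, thicknesses "
      + ", ".join(f"{t:.1f}" for t in stack.thicknesses_mm) + " mm")

transforms = []
for s in stack.sections:
    tf, rms = ds.fit_similarity_transform(s.landmarks_section_mm, s.landmarks_reference_mm)
    transforms.append(tf)
print(f"registered each section from its landmarks "
      f"(last fit: rot {transforms[-1].rotation_deg:+.1f} deg, "
      f"scale {transforms[-1].scale:.3f}, rms {rms:.3f} mm)")

rebuilt = ds.stack_sections(stack, transforms, stack.true_gap_spacings_mm)
tumor_rec = ds.resample_labels(rebuilt, vol).grid == ds.TUMOR

v_true = phantom.tumor_mask.sum() * vol.voxel_volume_mm3
v_rec = tumor_rec.sum() * vol.voxel_volume_mm3
res = ds.under_over_95hd(phantom.tumor_mask, tumor_rec, vol.spacing_mm, vol.origin_mm)
print(f"tumor volume: true {v_true:.0f} mm^3, rebuilt {v_rec:.0f} mm^3 "
      f"({100 * (v_rec / v_true - 1):+.1f}%)")
print(f"tumor 95HD: underestimation {res.u95hd_mm:.2f} mm, "
      f"overestimation {res.o95hd_mm:.2f} mm")
print("\nBoth distances stay below the mean section thickness: stacking a few")
print("sparse sections cannot localize the tumor boundary any finer than that.")
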