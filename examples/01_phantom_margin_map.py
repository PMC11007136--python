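"""Generate a phantom specimen and map its resection margins in 3D.

Builds a synthetic tongue-specimen phantom (ellipsoid with a mucosal cap
and an off-center tumor), extracts the outer surface, partitions it into
the five conventional margin regions, and reports the per-region minimum
tumor-to-surface distance with the 5 mm adequacy call. The phantom's
brute-force ground truth is printed alongside for comparison; the two
should agree within about one voxel diagonal.
"""

import digispec as ds

config = ds.PhantomConfig(
    specimen_axes_mm=(14, 20, 12),
    tumor_axes_mm=(5, 6, 4),
    tumor_center_mm=(1.0, 2.0, -2.0),
    spacing_mm=0.5,
    seed=1,
)
phantom = ds.generate_phantom(config)
specimen = ds.make_digital_specimen(phantom.volume, role="ground-truth")

plane = ds.fit_mucosa_plane(specimen)
cone = ds.build_deep_cone(specimen, plane)
partition = ds.partition_surface(
    specimen, cone, phantom.anterior_point_mm, phantom.posterior_point_mm,
    phantom.craniomedial_hint,
)
margin_map = ds.compute_margin_map(specimen)
report = ds.classify_regions(margin_map, partition)

print(f"voxel spacing {config.spacing_mm} mm, "
      f"{specimen.outer_surface.n_vertices} surface vertices")
print(f"{'region':<14}{'pipeline mm':>12}{'truth mm':>10}  call")
for region in ds.REGIONS:
    print(f"{region:<14}{report.region_min_mm[region]:>12.2f}"
          f"{phantom.truth_margins[region]:>10.2f}  {report.calls[region]}")
print("\nA margin below 5 mm is 'inadequate' (the finding a surgeon acts on);")
print("pipeline and brute-force truth should differ by less than one voxel")
print(f"diagonal ({phantom.volume.voxel_diagonal_mm:.2f} mm here).")

ds.save_mesh(
    specimen.outer_surface, "scratch_margin_surface.ply",
    scalars={"margin_mm": margin_map.vertex_margin_mm, "region": partition.labels},
)
print("\nwrote scratch_margin_surface.ply (per-vertex margin_mm + region)")
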