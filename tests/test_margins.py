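"""Margin maps, region calls and the conventional slice-based rule."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

import digispec as ds
from digispec.errors import GridMismatchError, NoTumorSectionError
from digispec.margins import ADEQUATE, INADEQUATE, NOT_ASSESSABLE


@pytest.fixture(scope="module")
def concentric():
    ph = ds.generate_phantom(
        ds.PhantomConfig(specimen_axes_mm=(15, 15, 15), tumor_axes_mm=(10, 10, 10),
                         spacing_mm=0.5)
    )
    return ph, ds.make_digital_specimen(ph.volume)


class TestComputeMarginMap:
    def test_concentric_vertices_near_five(self, concentric):
        ph, gt = concentric
        mm = ds.compute_margin_map(gt)
        d = ph.volume.voxel_diagonal_mm
        vals = mm.included_margins
        assert np.all(np.abs(vals - 5.0) <= d)

    def test_tumor_touching_surface_min_below_diagonal(self):
        grid = np.zeros((20, 20, 20), dtype=np.int16)
        grid[3:17, 3:17, 3:17] = ds.SPECIMEN
        grid[8:12, 8:12, 3:12] = ds.TUMOR  # reaches the support boundary
        vol = ds.LabeledVolume(grid, (1, 1, 1), (0, 0, 0))
        spec = ds.make_digital_specimen(vol)
        mm = ds.compute_margin_map(spec)
        assert mm.min_margin_mm < vol.voxel_diagonal_mm

    def test_matches_bruteforce_nearest_voxel(self):
        for seed in range(10):
            ph = ds.generate_phantom(ds.random_phantom_config(300 + seed, spacing_mm=1.2))
            gt = ds.make_digital_specimen(ph.volume)
            mm = ds.compute_margin_map(gt, exclude_mucosa=False)
            tum_pts = ph.volume.origin_mm + np.argwhere(ph.tumor_mask) * ph.volume.spacing_mm
            brute = cKDTree(tum_pts).query(gt.outer_surface.vertices, workers=-1)[0]
            d = ph.volume.voxel_diagonal_mm
            assert np.abs(mm.vertex_margin_mm - brute).max() <= d

    def test_frame_mismatch(self, concentric):
        ph, gt = concentric
        df = ds.mask_distance_field(ph.tumor_mask, ph.volume)
        df.origin_mm = df.origin_mm + 1.0
        with pytest.raises(GridMismatchError):
            ds.compute_margin_map(gt, distance_field=df)


def synthetic_map_partition(values, region_names):
    mm = ds.MarginMap(
        vertex_margin_mm=np.asarray(values, dtype=float),
        excluded=np.isnan(np.asarray(values, dtype=float)),
    )
    codes = {n: i for i, n in enumerate(ds.REGIONS)}
    labels = np.array([codes[r] for r in region_names])
    plane = ds.Plane((0, 0, 0), (0, 0, 1))
    cone = ds.Cone((0, 0, 0), (0, 0, -1), 45.0)
    part = ds.RegionPartition(labels, plane, cone, np.zeros(3), np.ones(3), np.ones(3))
    return mm, part


class TestClassifyRegions:
    def test_strict_threshold(self):
        mm, part = synthetic_map_partition(
            [4.99, 5.0, 6.0, 7.0, 8.0],
            ["anterior", "posterior", "craniomedial", "caudolateral", "deep_central"],
        )
        rep = ds.classify_regions(mm, part)
        assert rep.calls["anterior"] == INADEQUATE   # 4.99 < 5.0
        assert rep.calls["posterior"] == ADEQUATE    # exactly 5.0 is adequate
        assert rep.region_min_mm["anterior"] == pytest.approx(4.99)

    def test_fully_excluded_region_not_assessable(self):
        mm, part = synthetic_map_partition(
            [np.nan, 5.5, 6.0, 7.0, 8.0],
            ["anterior", "posterior", "craniomedial", "caudolateral", "deep_central"],
        )
        rep = ds.classify_regions(mm, part)
        assert rep.calls["anterior"] == NOT_ASSESSABLE
        assert rep.region_min_mm["anterior"] is None

    def test_deep_invading_tumor_flags_only_deep(self):
        """Tall narrow tumor near the deep pole: deep inadequate, the other
        four regions adequate (generator-truth driven)."""
        ph = ds.generate_phantom(
            ds.PhantomConfig(
                specimen_axes_mm=(15, 19, 12),
                tumor_axes_mm=(2.5, 3, 6),
                tumor_center_mm=(0, 0, -3),
                spacing_mm=0.8,
            )
        )
        d = ph.volume.voxel_diagonal_mm
        assert ph.truth_margins["deep_central"] < 5.0 - d
        assert all(
            v > 5.0 + d for r, v in ph.truth_margins.items() if r != "deep_central"
        )
        gt = ds.make_digital_specimen(ph.volume)
        plane = ds.fit_mucosa_plane(gt)
        cone = ds.build_deep_cone(gt, plane)
        part = ds.partition_surface(
            gt, cone, ph.anterior_point_mm, ph.posterior_point_mm, ph.craniomedial_hint
        )
        rep = ds.classify_regions(ds.compute_margin_map(gt), part)
        assert rep.calls["deep_central"] == INADEQUATE
        for region in ("anterior", "posterior", "craniomedial", "caudolateral"):
            assert rep.calls[region] == ADEQUATE

    def test_min_over_regions_is_global_min(self, concentric, offset_phantom,
                                            offset_specimen, offset_partition):
        mm = ds.compute_margin_map(offset_specimen)
        rep = ds.classify_regions(mm, offset_partition)
        mins = [v for v in rep.region_min_mm.values() if v is not None]
        assert min(mins) == pytest.approx(mm.min_margin_mm)

    def test_monotone_under_tumor_dilation(self, offset_phantom, offset_specimen,
                                           offset_partition):
        vol = offset_phantom.volume
        rep0 = ds.classify_regions(ds.compute_margin_map(offset_specimen), offset_partition)
        grown = ds.perturb_tumor_outline(
            offset_phantom.tumor_mask, vol.spacing_mm, 2.0, 0.0, 0,
            specimen_mask=offset_phantom.specimen_support,
        )
        spec2 = ds.DigitalSpecimen(
            outer_surface=offset_specimen.outer_surface,
            tumor_mask=grown,
            mucosa_vertex_flags=offset_specimen.mucosa_vertex_flags,
            volume=vol,
        )
        rep2 = ds.classify_regions(ds.compute_margin_map(spec2), offset_partition)
        for region in ds.REGIONS:
            assert rep2.region_min_mm[region] <= rep0.region_min_mm[region] + 1e-9


def box_volume_with_tumor(y_tumor_lo, y_tumor_hi, ny=43, h=1.0):
    """Rectangular specimen spanning ny mm with a tumor slab in y range."""
    grid = np.zeros((24, ny + 4, 20), dtype=np.int16)
    grid[4:20, 2:2 + ny, 4:16] = ds.SPECIMEN
    grid[8:16, 2 + y_tumor_lo:2 + y_tumor_hi, 6:12] = ds.TUMOR
    return ds.LabeledVolume(grid, (h, h, h), (0, 0, 0))


class TestConventionalSliceMargins:
    def test_one_free_anterior_section_case(self):
        """One tumor-free block at the anterior end with mean thickness
        4.3 mm reports a 4.3 mm anterior margin - inadequate."""
        vol = box_volume_with_tumor(0, 39, ny=43)  # free: y in [39, 43)
        rep = ds.conventional_slice_margins(vol, mean_thickness_mm=4.3)
        assert rep.n_sections == 10
        assert rep.mean_thickness_mm == pytest.approx(4.3)
        assert rep.anterior_mm == pytest.approx(4.3)
        assert rep.calls["anterior"] == INADEQUATE

    def test_tumor_in_first_section_zero_margin(self):
        vol = box_volume_with_tumor(0, 43, ny=43)
        rep = ds.conventional_slice_margins(vol, mean_thickness_mm=4.3)
        assert rep.anterior_mm == 0.0
        assert rep.posterior_mm == 0.0

    def test_margins_are_thickness_multiples(self):
        vol = box_volume_with_tumor(10, 25, ny=43)
        rep = ds.conventional_slice_margins(vol, mean_thickness_mm=4.3)
        for v in (rep.anterior_mm, rep.posterior_mm):
            assert v / rep.mean_thickness_mm == pytest.approx(round(v / rep.mean_thickness_mm))

    def test_no_tumor_raises(self):
        grid = np.zeros((10, 10, 10), dtype=np.int16)
        grid[2:8, 2:8, 2:8] = ds.SPECIMEN
        with pytest.raises(NoTumorSectionError):
            ds.conventional_slice_margins(ds.LabeledVolume(grid, (1, 1, 1), (0, 0, 0)))

    def test_consistent_with_3d_margins_on_aligned_phantom(self, offset_phantom):
        """Jitter-free sectioning: sector margins within one section
        thickness of the 3D per-region margins; anterior/posterior within
        one thickness of the axis-aligned truth."""
        ph = offset_phantom
        rep = ds.conventional_slice_margins(ph.volume, mean_thickness_mm=4.0)
        t = rep.mean_thickness_mm
        for region in ("craniomedial", "caudolateral", "deep_central"):
            assert rep.sector_min_mm[region] == pytest.approx(
                ph.truth_margins[region], abs=t
            )
        cfg = ph.config
        ant_truth = cfg.specimen_axes_mm[1] - (cfg.tumor_center_mm[1] + cfg.tumor_axes_mm[1])
        post_truth = cfg.specimen_axes_mm[1] + (cfg.tumor_center_mm[1] - cfg.tumor_axes_mm[1])
        assert rep.anterior_mm == pytest.approx(ant_truth, abs=t)
        assert rep.posterior_mm == pytest.approx(post_truth, abs=t)


def test_colormap_spec_marks_threshold():
    spec = ds.margin_colormap_spec(5.0)
    assert spec["threshold_mm"] == 5.0
    assert spec["stops"][0]["color"] == spec["below_threshold_color"]
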