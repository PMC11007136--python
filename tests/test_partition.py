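"""Five-region surface partition: plane fit, cone, quadrant assignment."""

from types import SimpleNamespace

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import digispec as ds
from digispec.errors import ConeGeometryError, MucosaFitError


def classify_vertex(p, apex, axis, e1, e2, half_angle_deg, cm_is_plus_e2):
    """Scalar reference classifier, same definitions as the pipeline."""
    v = p - apex
    nv = np.linalg.norm(v)
    proj = float(v @ axis)
    if proj > 0 and (nv == 0 or proj / nv >= np.cos(np.deg2rad(half_angle_deg)) - 1e-12):
        return "deep_central"
    az = np.degrees(np.arctan2(float(v @ e2), float(v @ e1))) % 360.0
    if az >= 315.0 or az < 45.0:
        return "anterior"
    if 135.0 <= az < 225.0:
        return "posterior"
    if 45.0 <= az < 135.0:
        return "craniomedial" if cm_is_plus_e2 else "caudolateral"
    return "caudolateral" if cm_is_plus_e2 else "craniomedial"


class TestMucosaPlane:
    def test_exactly_coplanar(self, offset_specimen):
        verts = offset_specimen.outer_surface.vertices.copy()
        n_true = np.array([0.3, 0.1, 0.94])
        n_true = n_true / np.linalg.norm(n_true)
        flags = np.zeros(len(verts), dtype=bool)
        flags[:200] = True
        # project flagged vertices onto a known plane through (0,0,8)
        pts = verts[:200]
        pts = pts - np.outer((pts - [0, 0, 8]) @ n_true, n_true)
        verts[:200] = pts
        spec = SimpleNamespace(
            outer_surface=SimpleNamespace(vertices=verts), mucosa_vertex_flags=flags
        )
        plane = ds.fit_mucosa_plane(spec)
        assert abs(abs(plane.unit_normal @ n_true) - 1.0) < 1e-9
        assert np.abs(plane.signed_distance(pts)).max() < 1e-9

    def test_tls_recovery_under_noise(self):
        rng = np.random.default_rng(0)
        n_true = np.array([0.2, -0.1, 0.97])
        n_true /= np.linalg.norm(n_true)
        basis = np.linalg.svd(n_true[None])[2][1:]
        pts = rng.uniform(-10, 10, (500, 2)) @ basis + rng.normal(0, 0.2, (500, 1)) * n_true
        pts += [0, 0, 10]
        flags = np.ones(500, dtype=bool)
        # interior below the plane so the normal orients downward
        verts = np.vstack([pts, pts - 15 * n_true])
        spec = SimpleNamespace(
            outer_surface=SimpleNamespace(vertices=verts),
            mucosa_vertex_flags=np.concatenate([flags, np.zeros(500, dtype=bool)]),
        )
        plane = ds.fit_mucosa_plane(spec)
        angle = np.degrees(np.arccos(np.clip(abs(plane.unit_normal @ n_true), -1, 1)))
        assert angle < 2.0
        assert plane.unit_normal @ n_true < 0  # oriented toward the interior

    def test_phantom_deep_direction(self, offset_specimen):
        plane = ds.fit_mucosa_plane(offset_specimen)
        angle = np.degrees(np.arccos(np.clip(plane.unit_normal @ [0, 0, -1], -1, 1)))
        assert angle < 15.0

    def test_too_few_mucosa_vertices(self, offset_specimen):
        spec = SimpleNamespace(
            outer_surface=offset_specimen.outer_surface,
            mucosa_vertex_flags=np.zeros(offset_specimen.outer_surface.n_vertices, bool),
        )
        with pytest.raises(MucosaFitError):
            ds.fit_mucosa_plane(spec)


class TestDeepCone:
    def test_apex_at_tumor_centroid(self, offset_phantom, offset_specimen):
        plane = ds.fit_mucosa_plane(offset_specimen)
        cone = ds.build_deep_cone(offset_specimen, plane)
        idx = np.argwhere(offset_phantom.tumor_mask)
        centroid = offset_phantom.volume.world_from_index(idx.mean(axis=0))
        assert np.linalg.norm(cone.apex_mm - centroid) <= 0.5 * max(
            offset_phantom.volume.spacing_mm
        )

    def test_apex_override_exact(self, offset_specimen):
        plane = ds.fit_mucosa_plane(offset_specimen)
        cone = ds.build_deep_cone(offset_specimen, plane, apex_override=(1.0, 2.0, 3.0))
        np.testing.assert_array_equal(cone.apex_mm, [1.0, 2.0, 3.0])

    def test_membership_equals_2d_sector_test(self):
        """3D membership == sector test in any plane containing the axis."""
        rng = np.random.default_rng(1)
        cone = ds.Cone(apex_mm=(1.0, -2.0, 3.0), unit_axis=(0.1, 0.2, -0.95),
                       half_angle_deg=37.0)
        pts = rng.uniform(-20, 20, (500, 3))
        got = cone.contains(pts)
        v = pts - cone.apex_mm
        axial = v @ cone.unit_axis
        radial = np.linalg.norm(v - np.outer(axial, cone.unit_axis), axis=1)
        # 2D sector: axial > 0 and atan2(radial, axial) <= half-angle
        want = (axial > 0) & (
            np.degrees(np.arctan2(radial, axial)) <= 37.0 + 1e-9
        )
        np.testing.assert_array_equal(got, want)

    def test_invalid_half_angle(self):
        with pytest.raises(ConeGeometryError):
            ds.Cone(apex_mm=(0, 0, 0), unit_axis=(0, 0, 1), half_angle_deg=90.0)


class TestPartitionSurface:
    def test_anterior_direction_vertex(self, offset_phantom, offset_specimen, offset_partition):
        part = offset_partition
        verts = offset_specimen.outer_surface.vertices
        apex = part.cone.apex_mm
        ap = offset_phantom.anterior_point_mm - offset_phantom.posterior_point_mm
        ap = ap / np.linalg.norm(ap)
        scores = (verts - apex) @ ap / np.linalg.norm(verts - apex, axis=1)
        assert part.names[np.argmax(scores)] == "anterior"

    def test_cone_boundary_tie_breaks_deep(self):
        cone = ds.Cone(apex_mm=(0, 0, 0), unit_axis=(0, 0, -1), half_angle_deg=45.0)
        boundary_pt = np.array([[3.0, 0.0, -3.0]])  # exactly 45 degrees
        assert cone.contains(boundary_pt)[0]

    def test_partition_complete_and_exclusive(self, offset_partition, offset_specimen):
        labels = offset_partition.labels
        assert len(labels) == offset_specimen.outer_surface.n_vertices
        assert set(np.unique(labels)) == set(range(5))

    def test_matches_bruteforce_oracle_on_random_phantoms(self):
        for seed in range(10):
            ph = ds.generate_phantom(ds.random_phantom_config(200 + seed, spacing_mm=1.2))
            gt = ds.make_digital_specimen(ph.volume)
            plane = ds.fit_mucosa_plane(gt)
            cone = ds.build_deep_cone(gt, plane)
            part = ds.partition_surface(
                gt, cone, ph.anterior_point_mm, ph.posterior_point_mm, ph.craniomedial_hint
            )
            axis = cone.unit_axis
            ap = ph.anterior_point_mm - ph.posterior_point_mm
            e1 = ap - (ap @ axis) * axis
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(axis, e1)
            h = ph.craniomedial_hint - (ph.craniomedial_hint @ axis) * axis
            cm_plus = bool(h @ e2 > 0)
            expected = np.array([
                classify_vertex(p, cone.apex_mm, axis, e1, e2, 45.0, cm_plus)
                for p in gt.outer_surface.vertices
            ])
            assert (part.names == expected).all()

    def test_rigid_motion_equivariance(self, offset_phantom, offset_specimen, offset_partition):
        rot = Rotation.from_euler("xyz", [20, -35, 50], degrees=True)
        shift = np.array([5.0, -3.0, 7.0])
        verts = rot.apply(offset_specimen.outer_surface.vertices) + shift
        moved = SimpleNamespace(outer_surface=SimpleNamespace(vertices=verts))
        cone0 = offset_partition.cone
        cone = ds.Cone(
            apex_mm=rot.apply(cone0.apex_mm) + shift,
            unit_axis=rot.apply(cone0.unit_axis),
            half_angle_deg=cone0.half_angle_deg,
        )
        part = ds.partition_surface(
            moved,
            cone,
            rot.apply(offset_phantom.anterior_point_mm) + shift,
            rot.apply(offset_phantom.posterior_point_mm) + shift,
            rot.apply(offset_phantom.craniomedial_hint),
        )
        np.testing.assert_array_equal(part.labels, offset_partition.labels)

    def test_degenerate_reference_points(self, offset_specimen, offset_partition):
        cone = offset_partition.cone
        with pytest.raises(ConeGeometryError):
            ds.partition_surface(offset_specimen, cone, (0, 0, 0), (0, 0, 0), (1, 0, 0))
        with pytest.raises(ConeGeometryError):
            # anterior-posterior direction along the cone axis
            ds.partition_surface(
                offset_specimen, cone,
                cone.apex_mm + 10 * cone.unit_axis,
                cone.apex_mm - 10 * cone.unit_axis,
                (1, 0, 0),
            )
        with pytest.raises(ConeGeometryError):
            # hint parallel to the cone axis
            ds.partition_surface(
                offset_specimen, cone, (0, 20, 0), (0, -20, 0), cone.unit_axis
            )
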