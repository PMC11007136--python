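"""95HD under/overestimation and diagnostic accuracy statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

import digispec as ds
from digispec.errors import CallsMismatchError, EmptySupportError, GridMismatchError

from conftest import voxel_ball


def brute_force_phd(a, b, p):
    """Exhaustive all-pairs percentile Hausdorff (same definition)."""
    da = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)).min(axis=1)
    db = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)).min(axis=0)
    return max(np.percentile(da, p), np.percentile(db, p))


def clopper_pearson_oracle(k, n, alpha=0.05):
    """CI by direct numeric inversion of the binomial tail probabilities."""
    grid = np.linspace(1e-9, 1 - 1e-9, 200001)
    # lower bound: smallest p with P(X >= k | p) >= alpha/2 (sf increasing in p)
    lo = 0.0 if k == 0 else grid[np.argmax(binom.sf(k - 1, n, grid) >= alpha / 2)]
    # upper bound: largest p with P(X <= k | p) >= alpha/2 (cdf decreasing in p)
    hi = 1.0 if k == n else grid[np.sum(binom.cdf(k, n, grid) >= alpha / 2) - 1]
    return lo, hi


class TestBooleanIntersection:
    def test_idempotent_and_empty(self):
        rng = np.random.default_rng(0)
        a = rng.random((8, 8, 8)) < 0.3
        np.testing.assert_array_equal(ds.boolean_intersection(a, a), a)
        empty = np.zeros_like(a)
        assert not ds.boolean_intersection(a, empty).any()

    def test_offset_balls_inclusion_exclusion(self):
        a, sp, org = voxel_ball(5.0, 1.0, extent_mm=12.0)
        b, _, _ = voxel_ball(5.0, 1.0, center=(3.0, 0.0, 0.0), extent_mm=12.0)
        inter = ds.boolean_intersection(a, b)
        assert inter.sum() == a.sum() + b.sum() - (a | b).sum()

    def test_grid_mismatch(self):
        with pytest.raises(GridMismatchError):
            ds.boolean_intersection(np.zeros((3, 3, 3), bool), np.zeros((4, 3, 3), bool))


class TestPercentileHausdorff:
    def test_identical_sets_zero(self):
        pts = np.random.default_rng(1).uniform(0, 10, (50, 3))
        assert ds.percentile_hausdorff(pts, pts, 95) == 0.0

    def test_p100_is_classical_hausdorff(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 10, (40, 3))
        b = rng.uniform(0, 10, (30, 3))
        classical = brute_force_phd(a, b, 100)
        assert ds.percentile_hausdorff(a, b, 100) == pytest.approx(classical, abs=1e-12)

    def test_offset_balls_match_brute_force(self):
        a, sp, org = voxel_ball(4.0, 1.0, margin_mm=5.0)
        b, _, _ = voxel_ball(4.0, 1.0, margin_mm=5.0, center=(3.0, 0.0, 0.0))
        sa = ds.boundary_face_points(a, sp, org)
        sb = ds.boundary_face_points(b, sp, org)
        got = ds.percentile_hausdorff(sa, sb, 95)
        assert got == pytest.approx(brute_force_phd(sa, sb, 95), abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 5, (30, 3))
        b = rng.uniform(0, 5, (25, 3))
        assert ds.percentile_hausdorff(a, b, 95) == ds.percentile_hausdorff(b, a, 95)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(scale=st.floats(0.1, 20.0), p=st.floats(5.0, 100.0))
    def test_scales_linearly(self, scale, p):
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 5, (20, 3))
        b = rng.uniform(0, 5, (20, 3))
        base = ds.percentile_hausdorff(a, b, p)
        assert ds.percentile_hausdorff(a * scale, b * scale, p) == pytest.approx(
            scale * base, rel=1e-9
        )

    def test_empty_set_raises(self):
        with pytest.raises(EmptySupportError):
            ds.percentile_hausdorff(np.empty((0, 3)), np.ones((3, 3)), 95)


class TestUnderOver95HD:
    def test_superset_test_has_zero_underestimation(self):
        ref, sp, org = voxel_ball(5.0, 1.0, margin_mm=6.0)
        test = ds.perturb_tumor_outline(ref, sp, 2.0, 0.0, 0)
        res = ds.under_over_95hd(ref, test, sp, org)
        d = float(np.linalg.norm(sp))
        assert res.u95hd_mm <= d
        assert res.o95hd_mm == pytest.approx(2.0, abs=d)

    def test_equal_masks_both_near_zero(self):
        ref, sp, org = voxel_ball(5.0, 1.0)
        res = ds.under_over_95hd(ref, ref, sp, org)
        assert res.u95hd_mm == pytest.approx(0.0, abs=1e-12)
        assert res.o95hd_mm == pytest.approx(0.0, abs=1e-12)
        assert res.intersection_volume_mm3 == ref.sum() * 1.0

    def test_disjoint_masks_flagged(self):
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a[1, 1, 1] = True
        b[8, 8, 8] = True
        res = ds.under_over_95hd(a, b, (1, 1, 1))
        assert res.empty_intersection
        assert res.u95hd_mm is None and res.o95hd_mm is None

    def test_dilation_recovery_sweep(self):
        ref, sp, org = voxel_ball(5.0, 1.0, margin_mm=8.0)
        d = float(np.linalg.norm(sp))
        for b in (1.0, 2.0, 5.0):
            test = ds.perturb_tumor_outline(ref, sp, b, 0.0, 0)
            res = ds.under_over_95hd(ref, test, sp, org)
            assert res.u95hd_mm <= d
            assert abs(res.o95hd_mm - b) <= d


class TestDiagnosticAccuracy:
    def test_reconstructed_counts_reproduce_printed_metrics(self):
        rep = ds.accuracy_from_counts(16, 1, 11, 17)
        assert rep.sensitivity.percent == 94
        assert rep.specificity.percent == 61
        assert rep.ppv.percent == 59
        assert rep.npv.percent == 94

    def test_exact_ci_16_of_17(self):
        rep = ds.accuracy_from_counts(16, 1, 0, 0)
        assert rep.sensitivity.ci95_percent == (71, 100)

    def test_ci_matches_numeric_inversion_oracle(self):
        for k, n in ((16, 17), (17, 28), (15, 23), (20, 22), (0, 10), (10, 10)):
            rep = ds.accuracy_from_counts(k, n - k, 0, 0)
            lo, hi = rep.sensitivity.ci95
            olo, ohi = clopper_pearson_oracle(k, n)
            assert lo == pytest.approx(olo, abs=5e-5)
            assert hi == pytest.approx(ohi, abs=5e-5)

    def test_perfect_agreement_all_metrics_100(self):
        calls = np.array([True, True, False, False, True])
        rep = ds.diagnostic_accuracy(calls, calls)
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            assert getattr(rep, name).percent == 100

    def test_swap_duality(self):
        rng = np.random.default_rng(5)
        t = rng.random(45) < 0.5
        r = rng.random(45) < 0.4
        fwd = ds.diagnostic_accuracy(t, r)
        rev = ds.diagnostic_accuracy(r, t)
        assert fwd.sensitivity.value == rev.ppv.value
        assert fwd.specificity.value == rev.npv.value

    def test_zero_denominator_not_defined(self):
        rep = ds.diagnostic_accuracy([False, False], [False, False])
        assert rep.sensitivity.value is None
        assert rep.ppv.value is None
        assert rep.specificity.value == 1.0

    def test_mismatch_errors(self):
        with pytest.raises(CallsMismatchError):
            ds.diagnostic_accuracy([True], [True, False])
        with pytest.raises(CallsMismatchError):
            ds.diagnostic_accuracy([2, 1], [0, 1])


class TestReconstructConfusionMatrices:
    def test_unique_for_both_published_columns(self):
        assert ds.reconstruct_confusion_matrices((94, 61, 59, 94), 45) == [(16, 1, 11, 17)]
        assert ds.reconstruct_confusion_matrices((88, 71, 65, 91), 45) == [(15, 2, 8, 20)]

    def test_perfect_metrics_tiny_n(self):
        out = ds.reconstruct_confusion_matrices((100, 100, 100, 100), 2)
        assert out == [(1, 0, 0, 1)]
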