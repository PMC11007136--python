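"""Agreement between digital specimens.

Tumor-outline agreement uses the under/overestimation 95th-percentile
Hausdorff distance: with I the Boolean intersection of the reference
(pathologist) and test (radiologist) tumors,

* U95HD = 95HD(surface(reference), surface(I)) - how much tumor the test
  outline misses (underestimation),
* O95HD = 95HD(surface(test), surface(I)) - how much the test outline
  overshoots (overestimation).

Region-call agreement is summarised as a confusion matrix over
(specimen, region) slots (inadequate = positive) with sensitivity,
specificity, PPV and NPV, each with an exact (Clopper-Pearson) 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from statsmodels.stats.proportion import proportion_confint

from .errors import CallsMismatchError, EmptySupportError, GridMismatchError
from .surface import boundary_face_points


# -- voxel-mask geometry ---------------------------------------------------

def boolean_intersection(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Voxelwise AND of two masks on the same grid."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise GridMismatchError(f"mask shapes {a.shape} vs {b.shape}")
    return a & b


def percentile_hausdorff(
    points_a: np.ndarray, points_b: np.ndarray, percentile: float = 95.0
) -> float:
    """Symmetric p-th percentile Hausdorff distance between two point sets.

    The directed value from A to B is the p-th percentile, over points of
    A, of the nearest distance to B; the result is the maximum of the two
    directed values. p = 100 recovers the classical Hausdorff distance.
    """
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise EmptySupportError("empty point set in percentile Hausdorff distance")
    if not 0.0 < percentile <= 100.0:
        raise ValueError("percentile must lie in (0, 100]")
    d_ab = cKDTree(b).query(a, workers=-1)[0]
    d_ba = cKDTree(a).query(b, workers=-1)[0]
    return float(max(np.percentile(d_ab, percentile), np.percentile(d_ba, percentile)))


@dataclass
class ComparisonResult:
    """Under/overestimation percentile Hausdorff distances of two tumors."""

    u95hd_mm: Optional[float]
    o95hd_mm: Optional[float]
    percentile: float
    intersection_volume_mm3: float
    empty_intersection: bool = False


def under_over_95hd(
    reference_tumor: np.ndarray,
    test_tumor: np.ndarray,
    spacing_mm,
    origin_mm=None,
    percentile: float = 95.0,
) -> ComparisonResult:
    """U95HD / O95HD between a reference and a test tumor mask.

    Surfaces are the boundary voxel-face center point sets of the masks.
    A disjoint pair is reported as flagged not-defined distances (None)
    rather than an arbitrary large number.
    """
    ref = np.asarray(reference_tumor, dtype=bool)
    tst = np.asarray(test_tumor, dtype=bool)
    if ref.shape != tst.shape:
        raise GridMismatchError("tumor masks on different grids")
    if not ref.any() or not tst.any():
        raise EmptySupportError("empty tumor mask")
    spacing_mm = np.asarray(spacing_mm, dtype=float).reshape(3)
    origin_mm = np.zeros(3) if origin_mm is None else np.asarray(origin_mm, dtype=float)
    inter = ref & tst
    vol = float(inter.sum()) * float(np.prod(spacing_mm))
    if not inter.any():
        return ComparisonResult(None, None, percentile, 0.0, empty_intersection=True)
    s_ref = boundary_face_points(ref, spacing_mm, origin_mm)
    s_tst = boundary_face_points(tst, spacing_mm, origin_mm)
    s_int = boundary_face_points(inter, spacing_mm, origin_mm)
    return ComparisonResult(
        u95hd_mm=percentile_hausdorff(s_ref, s_int, percentile),
        o95hd_mm=percentile_hausdorff(s_tst, s_int, percentile),
        percentile=percentile,
        intersection_volume_mm3=vol,
    )


# -- diagnostic accuracy ---------------------------------------------------

def round_percent(fraction: float) -> int:
    """Printed-percent convention: half-up to one decimal, then to integer.

    Mirrors two-stage statistical-software reporting (e.g. 0.78496 ->
    78.5% -> 79%).
    """
    one_dp = np.floor(fraction * 1000.0 + 0.5) / 10.0
    return int(np.floor(one_dp + 0.5))


@dataclass
class ProportionEstimate:
    successes: int
    trials: int
    value: Optional[float]
    ci95: Optional[tuple]

    @property
    def percent(self) -> Optional[int]:
        return None if self.value is None else round_percent(self.value)

    @property
    def ci95_percent(self) -> Optional[tuple]:
        if self.ci95 is None:
            return None
        return (round_percent(self.ci95[0]), round_percent(self.ci95[1]))


def _proportion(successes: int, trials: int) -> ProportionEstimate:
    if trials == 0:
        return ProportionEstimate(successes, 0, None, None)
    lo, hi = proportion_confint(successes, trials, alpha=0.05, method="beta")
    lo = 0.0 if np.isnan(lo) else float(lo)
    hi = 1.0 if np.isnan(hi) else float(hi)
    return ProportionEstimate(successes, trials, successes / trials, (lo, hi))


@dataclass
class AccuracyReport:
    """Confusion counts plus sens/spec/PPV/NPV with exact binomial CIs."""

    tp: int
    fn: int
    fp: int
    tn: int
    sensitivity: ProportionEstimate
    specificity: ProportionEstimate
    ppv: ProportionEstimate
    npv: ProportionEstimate

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def as_dict(self) -> dict:
        out = {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn, "n": self.n}
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            est = getattr(self, name)
            out[name] = est.value
            out[f"{name}_ci95"] = est.ci95
        return out


def accuracy_from_counts(tp: int, fn: int, fp: int, tn: int) -> AccuracyReport:
    return AccuracyReport(
        tp=tp, fn=fn, fp=fp, tn=tn,
        sensitivity=_proportion(tp, tp + fn),
        specificity=_proportion(tn, tn + fp),
        ppv=_proportion(tp, tp + fp),
        npv=_proportion(tn, tn + fn),
    )


def diagnostic_accuracy(
    test_calls: Sequence[bool], reference_calls: Sequence[bool]
) -> AccuracyReport:
    """Accuracy of binary region calls against a reference standard.

    Calls are ordered over the same (specimen, region) slots; True means
    inadequate (< threshold), the positive finding. Ratios with a zero
    denominator are reported as not-defined, never as 0.
    """
    t = np.asarray(test_calls)
    r = np.asarray(reference_calls)
    if t.shape != r.shape or t.ndim != 1:
        raise CallsMismatchError(f"call sequences {t.shape} vs {r.shape}")
    for arr in (t, r):
        if not (np.isin(arr, [0, 1]).all() or arr.dtype == bool):
            raise CallsMismatchError("calls must be binary")
    t = t.astype(bool)
    r = r.astype(bool)
    tp = int(np.sum(t & r))
    fn = int(np.sum(~t & r))
    fp = int(np.sum(t & ~r))
    tn = int(np.sum(~t & ~r))
    return accuracy_from_counts(tp, fn, fp, tn)


def reconstruct_confusion_matrices(
    percent_metrics: Sequence[int], n: int
) -> list:
    """All integer confusion matrices reproducing four printed percentages.

    ``percent_metrics`` is (sensitivity, specificity, PPV, NPV) as integer
    percents; the search enumerates every nonnegative (TP, FN, FP, TN)
    with TP+FN+FP+TN = n whose metrics round (printed-percent convention)
    to the given values. Published accuracy tables print the metrics but
    not the counts; a unique reconstruction recovers the underlying data.
    """
    want = tuple(int(v) for v in percent_metrics)
    out = []
    for tp in range(n + 1):
        for fn in range(n + 1 - tp):
            for fp in range(n + 1 - tp - fn):
                tn = n - tp - fn - fp
                metrics = []
                ok = True
                for k, m in ((tp, tp + fn), (tn, tn + fp), (tp, tp + fp), (tn, tn + fn)):
                    if m == 0:
                        ok = False
                        break
                    metrics.append(round_percent(k / m))
                if ok and tuple(metrics) == want:
                    out.append((tp, fn, fp, tn))
    return out
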