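"""Point-based 2D similarity registration and section stacking.

Histology sections arrive rotated, translated and (through tissue
shrinkage) scaled relative to the imaging frame. Corresponding anatomical
points picked on a section and on its matching reference slice determine a
least-squares similarity transform (rotation + isotropic scale +
translation, reflection excluded); registered sections are then stacked at
adjustable out-of-plane spacings into a label volume using a slab model:
labels are categorical, so inter-section voxels replicate the nearest
section rather than interpolate, mirroring how a single stained section
stands in for its whole 3-5 mm tissue block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import SimilarityTransform as _SkSimilarity

from .errors import (
    DegenerateLandmarksError,
    LandmarkCountError,
    StackConsistencyError,
)
from .volume import LabeledVolume


@dataclass
class SimilarityTransform2D:
    """Rotation (deg, counter-clockwise), isotropic scale > 0, translation (mm).

    Maps points as ``scale * R(rotation) @ p + translation``.
    """

    rotation_deg: float = 0.0
    scale: float = 1.0
    translation_mm: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self):
        if self.scale <= 0:
            raise DegenerateLandmarksError(f"scale {self.scale} must be positive")
        self.translation_mm = np.asarray(self.translation_mm, dtype=float).reshape(2)

    @property
    def matrix(self) -> np.ndarray:
        th = np.deg2rad(self.rotation_deg)
        r = self.scale * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        m = np.eye(3)
        m[:2, :2] = r
        m[:2, 2] = self.translation_mm
        return m

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return pts @ self.matrix[:2, :2].T + self.translation_mm

    def inverse(self) -> "SimilarityTransform2D":
        th = np.deg2rad(self.rotation_deg)
        rinv = np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]]) / self.scale
        return SimilarityTransform2D(
            rotation_deg=-self.rotation_deg,
            scale=1.0 / self.scale,
            translation_mm=-(rinv @ self.translation_mm),
        )

    def compose(self, other: "SimilarityTransform2D") -> "SimilarityTransform2D":
        """self after other: (self . other)(p) = self(other(p))."""
        m = self.matrix @ other.matrix
        return _from_matrix(m)


def _from_matrix(m: np.ndarray) -> SimilarityTransform2D:
    a = m[:2, :2]
    scale = float(np.sqrt(abs(np.linalg.det(a))))
    rot = float(np.degrees(np.arctan2(a[1, 0], a[0, 0])))
    return SimilarityTransform2D(rotation_deg=rot, scale=scale, translation_mm=m[:2, 2])


@dataclass
class LandmarkSet:
    """Ordered 2D points in mm; correspondence between sets is by order."""

    points_mm: np.ndarray
    source: str = "section"  # "section" | "reference"

    def __post_init__(self):
        self.points_mm = np.atleast_2d(np.asarray(self.points_mm, dtype=float))

    def __len__(self) -> int:
        return len(self.points_mm)


def fit_similarity_transform(src, dst):
    """Least-squares similarity (Umeyama) mapping src points onto dst.

    Returns ``(SimilarityTransform2D, rms_mm)`` where rms is the root mean
    square residual of the fitted correspondences. Reflections are never
    produced. Requires >= 2 corresponding, non-coincident points.
    """
    s = src.points_mm if isinstance(src, LandmarkSet) else np.atleast_2d(np.asarray(src, float))
    d = dst.points_mm if isinstance(dst, LandmarkSet) else np.atleast_2d(np.asarray(dst, float))
    if len(s) != len(d):
        raise LandmarkCountError(f"{len(s)} source vs {len(d)} destination points")
    if len(s) < 2:
        raise LandmarkCountError("similarity fit needs at least 2 point pairs")
    if np.allclose(s, s[0], atol=1e-12) or np.allclose(d, d[0], atol=1e-12):
        raise DegenerateLandmarksError("all landmarks coincident")
    try:  # skimage >= 0.26
        fit = _SkSimilarity.from_estimate(s, d)
        ok = bool(fit)
    except AttributeError:  # pragma: no cover - older scikit-image
        fit = _SkSimilarity()
        ok = fit.estimate(s, d)
    if not ok or not np.all(np.isfinite(fit.params)):
        raise DegenerateLandmarksError("similarity estimation failed")
    tf = _from_matrix(np.asarray(fit.params))
    resid = tf.apply(s) - d
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return tf, rms


def stack_sections(
    stack,
    transforms: Sequence[SimilarityTransform2D],
    spacings_mm: Sequence[float],
    out_spacing_mm: float = None,
) -> LabeledVolume:
    """Resample registered sections into a labeled volume (slab model).

    Parameters
    ----------
    stack : SectionStack
    transforms : one per section, mapping section-frame mm -> reference mm.
    spacings_mm : one per gap (n_sections - 1), center-to-center distances
        along the stacking (anterior-posterior, +y) axis.
    out_spacing_mm : out-of-plane voxel size of the result; defaults to the
        sections' in-plane pixel size.

    Sections are placed at cumulative positions starting from the stack's
    recorded first-section center; each output y-slice copies the nearest
    section's registered image. The volume's y extent runs half a section
    thickness beyond the first and last centers.
    """
    sections = stack.sections
    n = len(sections)
    if len(transforms) != n:
        raise StackConsistencyError(f"{len(transforms)} transforms for {n} sections")
    spacings = np.asarray(spacings_mm, dtype=float).ravel()
    if len(spacings) != max(n - 1, 0):
        raise StackConsistencyError(f"{len(spacings)} spacings for {n - 1} gaps")
    if np.any(spacings <= 0):
        raise StackConsistencyError("section spacings must be positive (overlapping slabs)")

    px = sections[0].pixel_spacing_mm
    org2 = sections[0].origin_mm
    shape2 = sections[0].image.shape
    for s in sections:
        if s.image.shape != shape2 or not np.allclose(s.pixel_spacing_mm, px) \
                or not np.allclose(s.origin_mm, org2):
            raise StackConsistencyError("sections do not share one canvas geometry")

    hy = float(out_spacing_mm) if out_spacing_mm else float(min(px))
    centers = stack.first_center_y_mm + np.concatenate([[0.0], np.cumsum(spacings)])
    y_lo = centers[0] - sections[0].thickness_mm / 2.0
    y_hi = centers[-1] + sections[-1].thickness_mm / 2.0
    ny = max(1, int(round((y_hi - y_lo) / hy)))
    y_centers = y_lo + (np.arange(ny) + 0.5) * hy

    # registered in-plane image per section: ref(p) = section(T^-1 p)
    ix, kx = np.indices(shape2, dtype=float)
    ref_pts = np.stack([org2[0] + ix * px[0], org2[1] + kx * px[1]], axis=-1).reshape(-1, 2)
    registered = []
    for s, tf in zip(sections, transforms):
        src = tf.inverse().apply(ref_pts)
        coords = ((src - s.origin_mm) / px).T.reshape(2, *shape2)
        img = ndimage.map_coordinates(s.image, coords, order=0, mode="constant", cval=0)
        registered.append(img)

    nearest = np.abs(y_centers[:, None] - centers[None, :]).argmin(axis=1)
    grid = np.zeros((shape2[0], ny, shape2[1]), dtype=np.int16)
    for j, sec_idx in enumerate(nearest):
        grid[:, j, :] = registered[sec_idx]

    spacing = np.array([px[0], hy, px[1]])
    origin = np.array([org2[0], y_centers[0], org2[1]])
    return LabeledVolume(grid=grid, spacing_mm=spacing, origin_mm=origin)
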