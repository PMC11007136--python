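"""Labeled voxel volumes, NIfTI persistence and Euclidean distance fields.

Conventions used throughout the package:

* world coordinates are millimetres;
* voxel indices are 0-based, the center of voxel ``(i, j, k)`` sits at
  ``origin + index * spacing``;
* all voxel distances are measured center-to-center;
* label codes: 0 background, 1 specimen tissue, 2 tumor, 3 mucosa.
  The *specimen support* is the union of labels {1, 2, 3}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import (
    AbsentLabelError,
    GridMismatchError,
    NonIntegerDataError,
    NonPositiveSpacingError,
    UnknownLabelError,
)

BACKGROUND, SPECIMEN, TUMOR, MUCOSA = 0, 1, 2, 3
KNOWN_LABELS = frozenset({BACKGROUND, SPECIMEN, TUMOR, MUCOSA})

_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass
class LabeledVolume:
    """A 3D integer label grid with world geometry.

    Parameters
    ----------
    grid : ndarray of int, shape (nx, ny, nz)
        Label codes per voxel.
    spacing_mm : ndarray, shape (3,)
        Voxel edge lengths along each axis, strictly positive.
    origin_mm : ndarray, shape (3,)
        World position of the center of voxel (0, 0, 0).
    """

    grid: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray = field(default=None)

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise NonIntegerDataError(f"label grid dtype {self.grid.dtype} is not integer")
        unknown = set(np.unique(self.grid)) - KNOWN_LABELS
        if unknown:
            raise UnknownLabelError(f"unknown label codes {sorted(unknown)}")
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float).reshape(3)
        if np.any(self.spacing_mm <= 0):
            raise NonPositiveSpacingError(f"spacing {self.spacing_mm} has a non-positive component")
        if self.origin_mm is None:
            self.origin_mm = np.zeros(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(3)

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.grid.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def voxel_diagonal_mm(self) -> float:
        """Length of one voxel's space diagonal; the package's unit of
        discretization tolerance."""
        return float(np.linalg.norm(self.spacing_mm))

    def world_from_index(self, idx: np.ndarray) -> np.ndarray:
        return self.origin_mm + np.asarray(idx, dtype=float) * self.spacing_mm

    def index_from_world(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.origin_mm) / self.spacing_mm

    def mask(self, labels) -> np.ndarray:
        """Boolean support of one label code or an iterable of codes."""
        if np.isscalar(labels):
            labels = (labels,)
        return np.isin(self.grid, list(labels))

    @property
    def specimen_support(self) -> np.ndarray:
        return self.grid > 0

    def same_grid_as(self, other: "LabeledVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=atol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=atol)
        )

    def validate_semantics(self) -> None:
        """Check the label-semantics invariants.

        Tumor and mucosa are part of the specimen support by construction of
        the single-grid format; mucosa must additionally sit on the support
        boundary (at least one background 6-neighbour).
        """
        support = self.specimen_support
        interior = ndimage.binary_erosion(support, structure=_STRUCT6, border_value=0)
        boundary = support & ~interior
        muc = self.grid == MUCOSA
        if np.any(muc & ~boundary):
            raise UnknownLabelError("mucosa voxels found off the specimen boundary")


@dataclass
class DistanceField:
    """Per-voxel Euclidean distance in mm to the nearest voxel of a target label."""

    grid: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray
    target_label: int

    def sample(self, points_mm: np.ndarray, order: int = 1) -> np.ndarray:
        """Interpolate the field at world points (trilinear by default)."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        coords = (pts - self.origin_mm) / self.spacing_mm
        return ndimage.map_coordinates(self.grid, coords.T, order=order, mode="nearest")


# -- I/O -------------------------------------------------------------------

def save_labeled_volume(vol: LabeledVolume, path) -> None:
    """Write a labeled volume as a single-channel integer NIfTI file."""
    affine = np.eye(4)
    affine[:3, :3] = np.diag(vol.spacing_mm)
    affine[:3, 3] = vol.origin_mm
    img = nib.Nifti1Image(vol.grid.astype(np.int16), affine)
    img.header.set_data_dtype(np.int16)
    nib.save(img, str(path))


def load_labeled_volume(path) -> LabeledVolume:
    """Read a labeled volume from NIfTI.

    Spacing is taken from the header zooms, origin from the affine
    translation. Raises distinct errors for a missing file, non-integer
    data, unknown labels and non-positive spacing.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    img = nib.load(str(p))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.all(data == np.round(data)):
            raise NonIntegerDataError(f"{p}: voxel data are not integral")
        data = data.astype(np.int16)
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    if np.any(spacing <= 0):
        raise NonPositiveSpacingError(f"{p}: spacing {spacing}")
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return LabeledVolume(grid=data.astype(np.int16), spacing_mm=spacing, origin_mm=origin)


# -- distance fields -------------------------------------------------------

def euclidean_distance_field(vol: LabeledVolume, target_label: int) -> DistanceField:
    """Exact Euclidean distance transform to a target label.

    Each voxel holds the distance in mm from its center to the nearest voxel
    center carrying ``target_label``, honouring anisotropic spacing.
    """
    target = vol.grid == target_label
    if not target.any():
        raise AbsentLabelError(f"label {target_label} absent from grid")
    dist = ndimage.distance_transform_edt(~target, sampling=vol.spacing_mm)
    return DistanceField(
        grid=dist,
        spacing_mm=vol.spacing_mm,
        origin_mm=vol.origin_mm,
        target_label=int(target_label),
    )


def mask_distance_field(mask: np.ndarray, like: LabeledVolume) -> DistanceField:
    """Distance field to an arbitrary boolean mask on the geometry of ``like``."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != like.shape:
        raise GridMismatchError("mask shape does not match volume")
    if not mask.any():
        raise AbsentLabelError("mask is empty")
    dist = ndimage.distance_transform_edt(~mask, sampling=like.spacing_mm)
    return DistanceField(grid=dist, spacing_mm=like.spacing_mm, origin_mm=like.origin_mm, target_label=-1)


def resample_labels(vol: LabeledVolume, like: LabeledVolume) -> LabeledVolume:
    """Nearest-neighbour resampling of a label volume onto another grid."""
    idx = np.indices(like.shape, dtype=float)
    world = like.origin_mm.reshape(3, 1, 1, 1) + idx * like.spacing_mm.reshape(3, 1, 1, 1)
    src = (world - vol.origin_mm.reshape(3, 1, 1, 1)) / vol.spacing_mm.reshape(3, 1, 1, 1)
    out = ndimage.map_coordinates(vol.grid, src, order=0, mode="constant", cval=BACKGROUND)
    return LabeledVolume(grid=out.astype(vol.grid.dtype), spacing_mm=like.spacing_mm, origin_mm=like.origin_mm)
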