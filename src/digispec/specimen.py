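"""The digital specimen: outer surface + tumor support + mucosa flags.

A digital specimen pairs one observer's tumor outline with the specimen's
outer contour. In the imaging workflow the outer contour always comes from
the MR volume — also for the histology-derived specimen, to compensate for
processing artifacts — so different observers of the same case share one
surface and differ only in their tumor masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import AbsentLabelError, GridMismatchError
from .surface import SurfaceMesh, extract_surface
from .volume import MUCOSA, LabeledVolume, mask_distance_field


@dataclass
class DigitalSpecimen:
    """One specimen / one observer.

    Attributes
    ----------
    outer_surface : SurfaceMesh
        Watertight resection-specimen contour, world mm.
    tumor_mask : ndarray of bool
        Tumor voxel support on ``volume``'s grid.
    mucosa_vertex_flags : ndarray of bool, len n_vertices
        True where a surface vertex lies on mucosa (anatomical surface, not
        a resection plane; excluded from margin assessment).
    volume : LabeledVolume
        The grid the specimen lives on (geometry reference for fields).
    role : str
        "MR-DS", "HE-DS" or "ground-truth".
    observer_id : str
    """

    outer_surface: SurfaceMesh
    tumor_mask: np.ndarray
    mucosa_vertex_flags: np.ndarray
    volume: LabeledVolume
    role: str = "MR-DS"
    observer_id: str = ""

    def __post_init__(self):
        self.tumor_mask = np.asarray(self.tumor_mask, dtype=bool)
        self.mucosa_vertex_flags = np.asarray(self.mucosa_vertex_flags, dtype=bool)
        if len(self.mucosa_vertex_flags) != self.outer_surface.n_vertices:
            raise GridMismatchError("mucosa flag count != vertex count")
        if self.tumor_mask.shape != self.volume.shape:
            raise GridMismatchError("tumor mask shape != volume shape")
        if not self.tumor_mask.any():
            raise AbsentLabelError("tumor mask is empty")

    @property
    def tumor_centroid_mm(self) -> np.ndarray:
        idx = np.argwhere(self.tumor_mask)
        return self.volume.world_from_index(idx.mean(axis=0))

    def tumor_contained_fraction(self, n_samples: int = 256, seed: int = 0) -> float:
        """Fraction of sampled tumor voxel centers inside the outer surface.

        Sampling check for the containment invariant; 1.0 means every sampled
        center is enclosed.
        """
        idx = np.argwhere(self.tumor_mask)
        rng = np.random.default_rng(seed)
        take = idx if len(idx) <= n_samples else idx[rng.choice(len(idx), n_samples, replace=False)]
        pts = self.volume.world_from_index(take)
        return float(self.outer_surface.as_trimesh().contains(pts).mean())


def make_digital_specimen(
    vol: LabeledVolume,
    tumor_mask: Optional[np.ndarray] = None,
    role: str = "MR-DS",
    observer_id: str = "",
    smoothing: str = "on",
    mucosa_band_diagonals: float = 1.0,
) -> DigitalSpecimen:
    """Build a digital specimen from a labeled volume.

    The outer surface is extracted from the full specimen support; vertices
    within ``mucosa_band_diagonals`` voxel diagonals of a mucosa voxel center
    are flagged as mucosa. ``tumor_mask`` defaults to the volume's own tumor
    label (pass an observer's mask to represent that observer's outline).
    """
    surf = extract_surface(vol, support_labels=(1, 2, 3), smoothing=smoothing)
    if tumor_mask is None:
        tumor_mask = vol.grid == 2
    muc = vol.grid == MUCOSA
    if muc.any():
        df = mask_distance_field(muc, vol)
        flags = df.sample(surf.vertices) <= mucosa_band_diagonals * vol.voxel_diagonal_mm
    else:
        flags = np.zeros(surf.n_vertices, dtype=bool)
    return DigitalSpecimen(
        outer_surface=surf,
        tumor_mask=np.asarray(tumor_mask, dtype=bool),
        mucosa_vertex_flags=np.asarray(flags, dtype=bool),
        volume=vol,
        role=role,
        observer_id=observer_id,
    )
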