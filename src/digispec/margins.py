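"""Margin maps, per-region adequacy calls and the conventional slice rule.

A resection margin is the distance from tumor to the cut specimen surface;
clinical practice calls a margin adequate at >= 5 mm and inadequate below.
Mucosa is an anatomical surface rather than a resection plane, so
mucosa-flagged vertices are excluded from assessment (configurable).

Two assessment routes are implemented:

* the 3D route — per-vertex tumor distances on the outer surface, reduced
  to per-region minima over the five-region partition;
* the conventional route — the slice-based rule a pathologist applies:
  anterior/posterior margins count tumor-free blocks times the mean block
  thickness, and on each tumor-bearing cross-section the in-plane minimum
  distances are read inside a 45-degree deep wedge and the two lateral
  sectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import GridMismatchError, NoTumorSectionError
from .partition import REGIONS, RegionPartition
from .specimen import DigitalSpecimen
from .volume import DistanceField, LabeledVolume, MUCOSA, TUMOR, mask_distance_field

ADEQUATE, INADEQUATE, NOT_ASSESSABLE = "adequate", "inadequate", "not_assessable"
DEFAULT_THRESHOLD_MM = 5.0


@dataclass
class MarginMap:
    """Per-vertex margin distances (mm) on an outer surface.

    Excluded (mucosa) vertices carry NaN.
    """

    vertex_margin_mm: np.ndarray
    excluded: np.ndarray
    threshold_mm: float = DEFAULT_THRESHOLD_MM

    def __post_init__(self):
        if self.threshold_mm <= 0:
            raise ValueError("threshold must be positive")

    @property
    def included_margins(self) -> np.ndarray:
        return self.vertex_margin_mm[~self.excluded]

    @property
    def min_margin_mm(self) -> float:
        vals = self.included_margins
        return float(np.min(vals)) if vals.size else float("nan")


@dataclass
class MarginReport:
    """Per-region minimum margins and adequacy calls at a strict threshold."""

    region_min_mm: dict                   # region -> float | None
    calls: dict                           # region -> adequate|inadequate|not_assessable
    threshold_mm: float = DEFAULT_THRESHOLD_MM

    def positive_calls(self) -> dict:
        """Binary view: True = inadequate (the 'positive' finding)."""
        return {r: c == INADEQUATE for r, c in self.calls.items() if c != NOT_ASSESSABLE}


def compute_margin_map(
    specimen: DigitalSpecimen,
    distance_field: Optional[DistanceField] = None,
    threshold_mm: float = DEFAULT_THRESHOLD_MM,
    exclude_mucosa: bool = True,
) -> MarginMap:
    """Tumor distance at every outer-surface vertex (trilinear sampling).

    ``distance_field`` must live on the specimen's grid and target its
    tumor; when omitted it is computed from ``specimen.tumor_mask``.
    """
    if distance_field is None:
        distance_field = mask_distance_field(specimen.tumor_mask, specimen.volume)
    else:
        vol = specimen.volume
        if (
            distance_field.grid.shape != vol.shape
            or not np.allclose(distance_field.spacing_mm, vol.spacing_mm)
            or not np.allclose(distance_field.origin_mm, vol.origin_mm)
        ):
            raise GridMismatchError("distance field frame differs from the specimen grid")
    margins = distance_field.sample(specimen.outer_surface.vertices).astype(float)
    excluded = specimen.mucosa_vertex_flags.copy() if exclude_mucosa \
        else np.zeros(specimen.outer_surface.n_vertices, dtype=bool)
    margins[excluded] = np.nan
    return MarginMap(vertex_margin_mm=margins, excluded=excluded, threshold_mm=threshold_mm)


def classify_regions(margin_map: MarginMap, partition: RegionPartition) -> MarginReport:
    """Per-region minimum margin; inadequate iff strictly below threshold.

    A region whose vertices are all excluded is reported not-assessable,
    never silently adequate.
    """
    if len(margin_map.vertex_margin_mm) != len(partition.labels):
        raise GridMismatchError("margin map and partition refer to different surfaces")
    region_min, calls = {}, {}
    names = partition.names
    for region in REGIONS:
        sel = (names == region) & ~margin_map.excluded
        if not sel.any():
            region_min[region] = None
            calls[region] = NOT_ASSESSABLE
            continue
        m = float(np.min(margin_map.vertex_margin_mm[sel]))
        region_min[region] = m
        calls[region] = INADEQUATE if m < margin_map.threshold_mm else ADEQUATE
    return MarginReport(region_min_mm=region_min, calls=calls, threshold_mm=margin_map.threshold_mm)


# -- conventional slice-based assessment -----------------------------------

@dataclass
class ConventionalReport:
    """Slice-based margins: block counting along the anterior-posterior axis
    and 45-degree sector minima on tumor-bearing cross-sections."""

    anterior_mm: float
    posterior_mm: float
    sector_min_mm: dict                   # craniomedial/caudolateral/deep_central -> mm
    calls: dict                           # all five regions
    mean_thickness_mm: float
    n_sections: int
    threshold_mm: float = DEFAULT_THRESHOLD_MM


def conventional_slice_margins(
    vol: LabeledVolume,
    mean_thickness_mm: float = 4.0,
    threshold_mm: float = DEFAULT_THRESHOLD_MM,
    deep_hint=(0.0, -1.0),
    craniomedial_hint=(1.0, 0.0),
    section_edges_mm: Optional[np.ndarray] = None,
) -> ConventionalReport:
    """Emulate conventional histopathological margin assessment.

    The volume is cut into coronal blocks. Anterior/posterior margins are
    (tumor-free block count at that end) x (specimen length / block count)
    — the quantized estimate pathology reports. On each tumor-bearing
    block's central cross-section, specimen-contour pixels are classified
    against two 45-degree lines through the tumor centroid oriented by the
    per-section mucosa chord (falling back to ``deep_hint`` in x-z when a
    section shows no mucosa): within the wedge -> deep central, otherwise
    craniomedial or caudolateral by the side of ``craniomedial_hint``.
    Sector margins aggregate across sections by minimum.
    """
    h = vol.spacing_mm
    support = vol.specimen_support
    jj = np.unique(np.argwhere(support)[:, 1])
    j0, j1 = jj.min(), jj.max()
    length = (j1 - j0 + 1) * h[1]
    if section_edges_mm is None:
        n = int(np.ceil(length / mean_thickness_mm))
        thickness = length / n
        edges = vol.origin_mm[1] + (j0 - 0.5) * h[1] + thickness * np.arange(n + 1)
    else:
        edges = np.asarray(section_edges_mm, dtype=float)
        n = len(edges) - 1
        thickness = length / n
    y_of_j = vol.origin_mm[1] + np.arange(vol.shape[1]) * h[1]
    block_of_j = np.clip(np.searchsorted(edges, y_of_j, side="right") - 1, 0, n - 1)
    tumor_any = np.array([
        bool((vol.grid[:, block_of_j == b, :] == TUMOR).any()) for b in range(n)
    ])
    if not tumor_any.any():
        raise NoTumorSectionError("no tumor-bearing section")
    first, last = np.argmax(tumor_any), n - 1 - np.argmax(tumor_any[::-1])
    # +y is anterior: anterior-free blocks sit at the high-index end
    anterior_mm = float((n - 1 - last) * thickness)
    posterior_mm = float(first * thickness)

    deep_hint = np.asarray(deep_hint, dtype=float)
    cm_hint = np.asarray(craniomedial_hint, dtype=float)
    spacing2 = np.array([h[0], h[2]])
    sector_min = {r: np.inf for r in ("craniomedial", "caudolateral", "deep_central")}
    struct4 = ndimage.generate_binary_structure(2, 1)
    for b in np.flatnonzero(tumor_any):
        js = np.flatnonzero(block_of_j == b)
        jc = js[len(js) // 2]
        sl = vol.grid[:, jc, :]
        tumor2d = sl == TUMOR
        if not tumor2d.any():  # tumor in block but not on its central section
            cand = [j for j in js if (vol.grid[:, j, :] == TUMOR).any()]
            jc = cand[len(cand) // 2]
            sl = vol.grid[:, jc, :]
            tumor2d = sl == TUMOR
        sup2d = sl > 0
        muc2d = sl == MUCOSA
        boundary = sup2d & ~ndimage.binary_erosion(sup2d, structure=struct4, border_value=0)
        contour = boundary & ~muc2d
        if not contour.any():
            continue
        c = np.argwhere(tumor2d).mean(axis=0) * spacing2
        if muc2d.any():
            mpts = np.argwhere(muc2d) * spacing2
            mc = mpts.mean(axis=0)
            centered = mpts - mc
            _, _, vt = np.linalg.svd(centered, full_matrices=False)
            chord = vt[0]
            deep = np.array([-chord[1], chord[0]])
            if np.dot(deep, mc - c) > 0:  # orient away from the mucosa
                deep = -deep
        else:
            deep = deep_hint / np.linalg.norm(deep_hint)
        side = np.array([-deep[1], deep[0]])
        if np.dot(side, cm_hint) < 0:
            side = -side
        dist2d = ndimage.distance_transform_edt(~tumor2d, sampling=spacing2)
        bpts = np.argwhere(contour)
        w = bpts * spacing2 - c
        nw = np.linalg.norm(w, axis=1)
        cos_deep = (w @ deep) / np.where(nw > 0, nw, 1.0)
        in_wedge = cos_deep >= np.cos(np.deg2rad(45.0))
        on_cm = (w @ side) >= 0
        d = dist2d[bpts[:, 0], bpts[:, 1]]
        for name, sel in (
            ("deep_central", in_wedge),
            ("craniomedial", ~in_wedge & on_cm),
            ("caudolateral", ~in_wedge & ~on_cm),
        ):
            if sel.any():
                sector_min[name] = min(sector_min[name], float(d[sel].min()))

    sector_min = {k: (None if np.isinf(v) else v) for k, v in sector_min.items()}
    calls = {
        "anterior": INADEQUATE if anterior_mm < threshold_mm else ADEQUATE,
        "posterior": INADEQUATE if posterior_mm < threshold_mm else ADEQUATE,
    }
    for name, v in sector_min.items():
        calls[name] = NOT_ASSESSABLE if v is None else (
            INADEQUATE if v < threshold_mm else ADEQUATE
        )
    return ConventionalReport(
        anterior_mm=anterior_mm,
        posterior_mm=posterior_mm,
        sector_min_mm=sector_min,
        calls=calls,
        mean_thickness_mm=float(thickness),
        n_sections=int(n),
        threshold_mm=threshold_mm,
    )


def margin_colormap_spec(threshold_mm: float = DEFAULT_THRESHOLD_MM) -> dict:
    """Portable colormap: continuous scale, dark red strictly below threshold.

    Renderers map per-vertex ``margin_mm`` through these control points
    (linear interpolation between stops; colors are sRGB in [0, 1]).
    """
    return {
        "channel": "margin_mm",
        "kind": "piecewise-linear",
        "below_threshold_color": [0.55, 0.0, 0.0],
        "stops": [
            {"value": 0.0, "color": [0.55, 0.0, 0.0]},
            {"value": threshold_mm, "color": [0.55, 0.0, 0.0]},
            {"value": threshold_mm + 1e-6, "color": [1.0, 0.9, 0.2]},
            {"value": 3 * threshold_mm, "color": [1.0, 1.0, 1.0]},
        ],
        "threshold_mm": threshold_mm,
    }
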