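"""Simulated histopathological sectioning with processing artifacts.

The specimen is cut into coronal blocks (perpendicular to the
anterior-posterior axis) of nominally 3-5 mm. The simulator reproduces the
artifact mechanisms that make conventional slice-based assessment diverge
from the 3D picture:

* **spacing jitter** — actual block thicknesses vary (reported range
  1-10 mm), so tumor-free-block counting misestimates margins;
* **differential shrinkage** — fixation shrinks healthy tissue more than
  tumor; sections are warped so tumor-to-edge distances contract by the
  shrink factor while the tumor itself is preserved;
* **rupture** — a random wedge of healthy tissue torn from one section;
* **arbitrary slide placement** — each section is rotated/translated on
  its slide; corresponding anatomical landmark pairs (section frame vs.
  reference frame) are recorded, along with the true placement transform,
  so registration can be validated against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List

import numpy as np
from scipy import ndimage

from .errors import SectionOrderError
from .phantom import Phantom
from .registration import SimilarityTransform2D
from .volume import TUMOR

_STRUCT4 = ndimage.generate_binary_structure(2, 1)


@dataclass
class Section:
    """One 2D label image in its own (slide) frame.

    ``true_transform`` maps slide-frame mm to reference (imaging) in-plane
    mm; ``landmarks_section_mm`` and ``landmarks_reference_mm`` are
    corresponding anatomical points in the two frames (order-matched).
    """

    image: np.ndarray                     # (nx, nz) int labels
    pixel_spacing_mm: np.ndarray          # (2,)
    origin_mm: np.ndarray                 # (2,) slide-frame position of pixel (0,0)
    thickness_mm: float
    landmarks_section_mm: np.ndarray      # (k, 2)
    landmarks_reference_mm: np.ndarray    # (k, 2)
    true_transform: SimilarityTransform2D
    true_center_y_mm: float


@dataclass
class SectionStack:
    sections: List[Section]
    mean_thickness_mm: float
    first_center_y_mm: float

    def __post_init__(self):
        for s in self.sections:
            if s.thickness_mm <= 0:
                raise SectionOrderError("non-positive section thickness")
            if len(s.landmarks_section_mm) < 3:
                raise SectionOrderError("fewer than 3 landmarks on a section")

    def __len__(self) -> int:
        return len(self.sections)

    @property
    def thicknesses_mm(self) -> np.ndarray:
        return np.array([s.thickness_mm for s in self.sections])

    @property
    def true_center_positions_mm(self) -> np.ndarray:
        return np.array([s.true_center_y_mm for s in self.sections])

    @property
    def true_gap_spacings_mm(self) -> np.ndarray:
        """Ground-truth center-to-center distances (input to stack_sections)."""
        return np.diff(self.true_center_positions_mm)


def _shrink_maps(slice_img: np.ndarray, spacing: np.ndarray, origin: np.ndarray, shrink: float):
    """Forward/inverse radial shrink about the tumor for one slice.

    Healthy tissue at tumor-distance d moves to distance ~shrink*d along the
    distance gradient; tumor pixels (d = 0) stay put, with a smooth blend in
    between. Returns (warp_points, inverse_coords_fn).
    """
    tumor = slice_img == TUMOR
    if tumor.any():
        d = ndimage.distance_transform_edt(~tumor, sampling=spacing)
        gx, gz = np.gradient(d, spacing[0], spacing[1])
        norm = np.hypot(gx, gz)
        with np.errstate(invalid="ignore"):
            ux = np.where(norm > 0, gx / norm, 0.0)
            uz = np.where(norm > 0, gz / norm, 0.0)

        def interp(f, pts):
            coords = ((pts - origin) / spacing).T
            return ndimage.map_coordinates(f, coords, order=1, mode="nearest")

        def warp_points(pts):  # forward: reference -> shrunk position
            dd = interp(d, pts)
            return pts - (1.0 - shrink) * dd[:, None] * np.stack(
                [interp(ux, pts), interp(uz, pts)], axis=1
            )

        def inverse_coords(pts):  # where a shrunk-frame point came from
            dd = interp(d, pts)
            return pts + (1.0 - shrink) / shrink * dd[:, None] * np.stack(
                [interp(ux, pts), interp(uz, pts)], axis=1
            )

    else:
        support = slice_img > 0
        c = origin + (np.argwhere(support).mean(axis=0) if support.any()
                      else np.array(slice_img.shape) / 2.0) * spacing

        def warp_points(pts):
            return c + shrink * (pts - c)

        def inverse_coords(pts):
            return c + (pts - c) / shrink

    return warp_points, inverse_coords


def _boundary_landmarks(slice_img: np.ndarray, spacing, origin, n_points: int = 8) -> np.ndarray:
    """Anatomical points: specimen-boundary pixels at spread azimuths."""
    support = slice_img > 0
    boundary = support & ~ndimage.binary_erosion(support, structure=_STRUCT4, border_value=0)
    pts = origin + np.argwhere(boundary) * spacing
    c = pts.mean(axis=0)
    az = np.arctan2(pts[:, 1] - c[1], pts[:, 0] - c[0])
    targets = np.linspace(-np.pi, np.pi, n_points, endpoint=False)
    picks = []
    for t in targets:
        diff = np.abs(np.angle(np.exp(1j * (az - t))))
        picks.append(pts[np.argmin(diff)])
    picks = np.unique(np.array(picks), axis=0)
    if len(picks) < 3:
        # tiny end section: use every distinct boundary pixel, then interior
        # pixel centers, so the similarity fit stays constrained
        extra = np.unique(pts, axis=0)
        picks = np.unique(np.vstack([picks, extra]), axis=0)
    if len(picks) < 3:
        interior = origin + np.argwhere(support) * spacing
        picks = np.unique(np.vstack([picks, interior]), axis=0)
    if len(picks) < 3:
        # degenerate 1-2 pixel section: half-pixel offsets still transform
        # rigidly with the slide and keep the correspondence valid
        offs = np.array([[0.5 * spacing[0], 0.0], [0.0, 0.5 * spacing[1]]])
        picks = np.vstack([picks] + [picks[:1] + o for o in offs])
    return picks


def simulate_sectioning(
    phantom: Phantom,
    mean_thickness_mm: float = 4.0,
    spacing_jitter_mm: float = 0.0,
    shrink_healthy: float = 1.0,
    rupture: bool = False,
    seed: int = 0,
    max_rotation_deg: float = 25.0,
    max_translation_mm: float = 3.0,
) -> SectionStack:
    """Cut a phantom into coronal sections with the artifact model above.

    Preconditions: ``mean_thickness_mm`` in [1, 10], ``shrink_healthy`` in
    (0.5, 1], ``spacing_jitter_mm < mean_thickness_mm`` (otherwise section
    order would be ambiguous). Deterministic for a fixed seed.
    """
    if not 1.0 <= mean_thickness_mm <= 10.0:
        raise ValueError(f"mean thickness {mean_thickness_mm} outside [1, 10] mm")
    if not 0.5 < shrink_healthy <= 1.0:
        raise ValueError(f"shrink factor {shrink_healthy} outside (0.5, 1]")
    if spacing_jitter_mm >= mean_thickness_mm:
        raise SectionOrderError(
            f"jitter {spacing_jitter_mm} >= mean thickness {mean_thickness_mm}"
        )
    vol = phantom.volume
    rng = np.random.default_rng(seed)
    h = vol.spacing_mm
    support = vol.specimen_support
    jj = np.unique(np.argwhere(support)[:, 1])
    j0, j1 = jj.min(), jj.max()
    y0 = vol.origin_mm[1] + j0 * h[1] - h[1] / 2.0
    length = (j1 - j0 + 1) * h[1]
    n_sections = int(np.ceil(length / mean_thickness_mm))
    if spacing_jitter_mm > 0:
        thick = rng.uniform(
            mean_thickness_mm - spacing_jitter_mm,
            mean_thickness_mm + spacing_jitter_mm,
            n_sections,
        )
    else:
        thick = np.full(n_sections, float(mean_thickness_mm))
    edges = y0 + np.concatenate([[0.0], np.cumsum(thick)])
    centers = (edges[:-1] + edges[1:]) / 2.0

    # shared slide canvas: the volume's x-z grid, padded so rotations and
    # translations cannot clip tissue
    pad = int(np.ceil(8.0 / min(h[0], h[2])))
    nx, nz = vol.shape[0], vol.shape[2]
    spacing2 = np.array([h[0], h[2]])
    origin2 = np.array([vol.origin_mm[0], vol.origin_mm[2]]) - pad * spacing2
    shape2 = (nx + 2 * pad, nz + 2 * pad)
    ix, kx = np.indices(shape2, dtype=float)
    canvas_pts = np.stack(
        [origin2[0] + ix * spacing2[0], origin2[1] + kx * spacing2[1]], axis=-1
    ).reshape(-1, 2)
    canvas_center = origin2 + (np.array(shape2) - 1) / 2.0 * spacing2

    rupture_idx = int(rng.integers(n_sections)) if rupture else -1

    y_of_j = vol.origin_mm[1] + np.arange(vol.shape[1]) * h[1]
    has_support = np.array([support[:, j, :].any() for j in range(vol.shape[1])])

    sections = []
    for i, (c_y, t) in enumerate(zip(centers, thick)):
        # representative slice: support-bearing slice nearest the block center
        in_block = (y_of_j >= edges[i]) & (y_of_j < edges[i + 1]) & has_support
        cand = np.flatnonzero(in_block)
        if cand.size == 0:
            continue  # jitter pushed this block past the specimen end
        j = int(cand[np.argmin(np.abs(y_of_j[cand] - c_y))])
        raw = np.zeros(shape2, dtype=np.int16)
        raw[pad:pad + nx, pad:pad + nz] = vol.grid[:, j, :]

        landmarks_ref = _boundary_landmarks(raw, spacing2, origin2)

        warp_points, inverse_coords = _shrink_maps(raw, spacing2, origin2, shrink_healthy)
        if shrink_healthy < 1.0:
            src = inverse_coords(canvas_pts)
            coords = ((src - origin2) / spacing2).T.reshape(2, *shape2)
            img = ndimage.map_coordinates(raw, coords, order=0, mode="constant", cval=0)
            lm_warped = warp_points(landmarks_ref)
        else:
            img = raw
            lm_warped = landmarks_ref.copy()

        if i == rupture_idx:
            img = _tear_wedge(img, spacing2, origin2, rng)

        tf = SimilarityTransform2D(
            rotation_deg=float(rng.uniform(-max_rotation_deg, max_rotation_deg)),
            scale=1.0,
            translation_mm=np.zeros(2),
        )
        # rotate about the canvas center, then translate
        shift = rng.uniform(-max_translation_mm, max_translation_mm, 2)
        offset = canvas_center - tf.apply(canvas_center)[0] + shift
        tf = SimilarityTransform2D(tf.rotation_deg, 1.0, offset)  # slide -> reference

        inv = tf.inverse()
        src = tf.apply(canvas_pts)  # slide pixel -> reference position
        coords = ((src - origin2) / spacing2).T.reshape(2, *shape2)
        slide_img = ndimage.map_coordinates(img, coords, order=0, mode="constant", cval=0)
        lm_slide = inv.apply(lm_warped)

        sections.append(
            Section(
                image=slide_img,
                pixel_spacing_mm=spacing2,
                origin_mm=origin2,
                thickness_mm=float(t),
                landmarks_section_mm=lm_slide,
                landmarks_reference_mm=landmarks_ref,
                true_transform=tf,
                true_center_y_mm=float(c_y),
            )
        )
    return SectionStack(
        sections=sections,
        mean_thickness_mm=float(mean_thickness_mm),
        first_center_y_mm=float(centers[0]),
    )


def _tear_wedge(img: np.ndarray, spacing, origin, rng, wedge_deg: float = 50.0) -> np.ndarray:
    """Remove a random angular wedge of healthy tissue (rupture artifact)."""
    out = img.copy()
    support = out > 0
    if not support.any():
        return out
    pts = np.argwhere(support)
    c = pts.mean(axis=0)
    ang = np.degrees(np.arctan2(pts[:, 1] - c[1], pts[:, 0] - c[0]))
    theta0 = rng.uniform(-180.0, 180.0)
    rel = (ang - theta0) % 360.0
    in_wedge = rel < wedge_deg
    # spare the tumor and its immediate neighbourhood
    tumor = out == TUMOR
    keep = ndimage.binary_dilation(tumor, iterations=2)
    sel = pts[in_wedge & ~keep[pts[:, 0], pts[:, 1]]]
    out[sel[:, 0], sel[:, 1]] = 0
    return out


def save_section_stack(stack: SectionStack, directory) -> None:
    """Sections as NPY label images plus one JSON manifest with thicknesses,
    landmark pairs and true transforms."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest = {
        "mean_thickness_mm": stack.mean_thickness_mm,
        "first_center_y_mm": stack.first_center_y_mm,
        "sections": [],
    }
    for i, s in enumerate(stack.sections):
        np.save(d / f"section_{i:03d}.npy", s.image)
        manifest["sections"].append(
            {
                "image": f"section_{i:03d}.npy",
                "pixel_spacing_mm": s.pixel_spacing_mm.tolist(),
                "origin_mm": s.origin_mm.tolist(),
                "thickness_mm": s.thickness_mm,
                "true_center_y_mm": s.true_center_y_mm,
                "landmarks_section_mm": s.landmarks_section_mm.tolist(),
                "landmarks_reference_mm": s.landmarks_reference_mm.tolist(),
                "true_transform": {
                    "rotation_deg": s.true_transform.rotation_deg,
                    "scale": s.true_transform.scale,
                    "translation_mm": s.true_transform.translation_mm.tolist(),
                },
            }
        )
    (d / "stack.json").write_text(json.dumps(manifest, indent=2))
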