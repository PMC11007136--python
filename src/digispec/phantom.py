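"""Synthetic specimen phantoms with known ground truth.

No imaging data accompany the study this package emulates, so validation
runs on phantoms: smoothed-ellipsoid specimens that fit the 59 mm-bore
scanning container, ellipsoidal tumors on the printed depth-of-invasion
scale (roughly 1-16 mm), a mucosal cap where the outward surface normal
points "up", and isotropic 0.3 mm voxels matching the 3D acquisition.
Every phantom carries brute-force ground-truth margins computed by dense
surface sampling, written independently of the pipeline's partition and
margin code so it can serve as an oracle for both.

Axis conventions: +y is the anterior-posterior axis (sections are coronal,
i.e. x-z planes); +z is "up" (the mucosal cap); +x is the craniomedial
hint direction for the two side quadrants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import (
    TumorAnnihilatedError,
    TumorOutsideSpecimenError,
    TumorUnresolvedError,
)
from .volume import MUCOSA, SPECIMEN, TUMOR, LabeledVolume, save_labeled_volume

CONTAINER_INNER_DIAMETER_MM = 59.0

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class PhantomConfig:
    """Geometry and discretization of one synthetic specimen.

    specimen_axes_mm : ellipsoid semi-axes (x, y, z); the x-z cross-section
        must fit the 59 mm container bore.
    tumor_center_mm : tumor ellipsoid center relative to the specimen center.
    tumor_axes_mm : tumor ellipsoid semi-axes.
    mucosa_cap_angle_deg : surface voxels whose outward normal is within
        this angle of +z are labeled mucosa.
    spacing_mm : isotropic voxel edge (default 0.3, the 3D sequence scale).
    bumpiness_mm : amplitude (std) of a smooth random radial perturbation
        of the specimen surface.
    pad_mm : background margin around the specimen so surfaces close and
        sections can rotate without clipping.
    """

    specimen_axes_mm: tuple = (14.0, 20.0, 12.0)
    tumor_center_mm: tuple = (0.0, 0.0, 0.0)
    tumor_axes_mm: tuple = (5.0, 6.0, 4.0)
    mucosa_cap_angle_deg: float = 60.0
    spacing_mm: float = 0.3
    seed: int = 0
    bumpiness_mm: float = 0.0
    pad_mm: float = 5.0


@dataclass
class Phantom:
    """A generated specimen plus its brute-force ground truth."""

    volume: LabeledVolume
    config: PhantomConfig
    truth_margins: dict                    # region name -> min distance (mm)
    truth_points_mm: np.ndarray            # dense non-mucosa surface samples
    truth_regions: np.ndarray              # per-sample region name
    anterior_point_mm: np.ndarray
    posterior_point_mm: np.ndarray
    craniomedial_hint: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    up_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.volume.grid == TUMOR

    @property
    def specimen_support(self) -> np.ndarray:
        return self.volume.specimen_support


def _smooth_directional_noise(rng: np.random.Generator, n: int = 9, sigma: float = 1.0):
    """A smooth scalar field on the unit sphere, sampled via a small 3D grid."""
    g = ndimage.gaussian_filter(rng.standard_normal((n, n, n)), sigma=sigma, mode="wrap")
    g = (g - g.mean()) / max(g.std(), 1e-12)

    def at(directions: np.ndarray) -> np.ndarray:
        # map unit vectors in [-1,1]^3 onto grid coordinates
        coords = (np.atleast_2d(directions).T + 1.0) * 0.5 * (n - 1)
        return ndimage.map_coordinates(g, coords, order=1, mode="nearest")

    return at


def generate_phantom(config: PhantomConfig) -> Phantom:
    """Deterministically voxelize a phantom and compute its ground truth.

    Raises
    ------
    TumorOutsideSpecimenError : tumor not strictly inside the specimen.
    TumorUnresolvedError : fewer than 3 voxels across any tumor axis.
    ValueError : specimen does not fit the container bore.
    """
    ax = np.asarray(config.specimen_axes_mm, dtype=float)
    t_ax = np.asarray(config.tumor_axes_mm, dtype=float)
    t_c = np.asarray(config.tumor_center_mm, dtype=float)
    h = float(config.spacing_mm)
    if np.any(2 * (ax[[0, 2]] + 3 * config.bumpiness_mm) > CONTAINER_INNER_DIAMETER_MM):
        raise ValueError("specimen cross-section exceeds the 59 mm container bore")
    if np.any(2 * t_ax / h < 3):
        raise TumorUnresolvedError(f"tumor axes {tuple(t_ax)} under 3 voxels at spacing {h}")

    rng = np.random.default_rng(config.seed)
    noise_at = _smooth_directional_noise(rng) if config.bumpiness_mm > 0 else None

    half = ax + 3 * config.bumpiness_mm + config.pad_mm
    n_vox = np.ceil(half / h).astype(int)
    spacing = np.array([h, h, h])
    origin = -n_vox * spacing
    shape = 2 * n_vox + 1
    idx = np.indices(shape, dtype=float)
    X = origin[0] + idx[0] * h
    Y = origin[1] + idx[1] * h
    Z = origin[2] + idx[2] * h

    r = np.sqrt(X**2 + Y**2 + Z**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        # ellipsoid radius along each voxel's direction
        u = np.stack([X, Y, Z]) / np.where(r > 0, r, 1.0)
        r_ell = 1.0 / np.sqrt((u[0] / ax[0]) ** 2 + (u[1] / ax[1]) ** 2 + (u[2] / ax[2]) ** 2)
    radius = r_ell
    if noise_at is not None:
        dirs = u.reshape(3, -1).T
        radius = r_ell + config.bumpiness_mm * noise_at(dirs).reshape(r.shape)
    support = r <= radius

    tumor = ((X - t_c[0]) / t_ax[0]) ** 2 + ((Y - t_c[1]) / t_ax[1]) ** 2 + (
        (Z - t_c[2]) / t_ax[2]
    ) ** 2 <= 1.0

    # strict containment: every tumor voxel and its 6-neighbourhood in support
    grown = ndimage.binary_dilation(tumor, structure=_STRUCT6)
    if np.any(grown & ~support):
        raise TumorOutsideSpecimenError("tumor support touches or crosses the specimen surface")

    interior = ndimage.binary_erosion(support, structure=_STRUCT6, border_value=0)
    boundary = support & ~interior

    # outward normals from the smoothed indicator gradient
    smooth = ndimage.gaussian_filter(support.astype(np.float32), sigma=1.5)
    grads = np.stack(np.gradient(smooth, h))
    bidx = np.argwhere(boundary)
    g = grads[:, bidx[:, 0], bidx[:, 1], bidx[:, 2]].T
    norms = np.linalg.norm(g, axis=1)
    outward = -g / np.where(norms > 0, norms, 1.0)[:, None]
    cos_up = outward[:, 2]  # up axis is +z
    cap = cos_up >= np.cos(np.deg2rad(config.mucosa_cap_angle_deg))

    grid = np.zeros(shape, dtype=np.int16)
    grid[support] = SPECIMEN
    muc = np.zeros(shape, dtype=bool)
    muc[bidx[cap, 0], bidx[cap, 1], bidx[cap, 2]] = True
    grid[muc & ~tumor] = MUCOSA
    grid[tumor] = TUMOR

    vol = LabeledVolume(grid=grid, spacing_mm=spacing, origin_mm=origin)

    # anterior / posterior reference points: support extremes along +-y,
    # tie-broken toward the specimen midline
    sup_idx = np.argwhere(support)
    world = origin + sup_idx * spacing
    for sign, name in ((+1, "ant"), (-1, "post")):
        yv = sign * world[:, 1]
        best = yv.max()
        cand = world[yv >= best - 1e-9]
        off = cand[:, [0, 2]] ** 2
        pick = cand[np.argmin(off.sum(axis=1))]
        if sign > 0:
            anterior = pick
        else:
            posterior = pick

    truth = _brute_force_truth(vol, tumor, boundary, muc, config)

    return Phantom(
        volume=vol,
        config=config,
        truth_margins=truth["margins"],
        truth_points_mm=truth["points"],
        truth_regions=truth["regions"],
        anterior_point_mm=anterior,
        posterior_point_mm=posterior,
    )


def _classify_point_truth(
    p: np.ndarray,
    apex: np.ndarray,
    axis: np.ndarray,
    e1: np.ndarray,
    e2: np.ndarray,
    half_angle_deg: float,
    cm_is_plus_e2: bool,
) -> str:
    """Scalar five-region rule, written independently of partition code."""
    v = p - apex
    nv = np.linalg.norm(v)
    proj = float(v @ axis)
    inside = proj > 0 and (nv == 0 or proj / nv >= np.cos(np.deg2rad(half_angle_deg)) - 1e-12)
    if inside:
        return "deep_central"
    az = np.degrees(np.arctan2(float(v @ e2), float(v @ e1))) % 360.0
    if az >= 315.0 or az < 45.0:
        return "anterior"
    if 135.0 <= az < 225.0:
        return "posterior"
    if 45.0 <= az < 135.0:
        return "craniomedial" if cm_is_plus_e2 else "caudolateral"
    return "caudolateral" if cm_is_plus_e2 else "craniomedial"


def _brute_force_truth(vol, tumor, boundary, mucosa, config) -> dict:
    """Dense-sampling ground truth: per-region minimum tumor-to-surface
    distance over all non-mucosa boundary voxel centers.

    Uses the phantom's exact deep axis (-z) rather than a fitted plane, and
    a per-point scalar classifier, so it is independent of the pipeline.
    """
    samples_idx = np.argwhere(boundary & ~mucosa)
    pts = vol.origin_mm + samples_idx * vol.spacing_mm
    tum_pts = vol.origin_mm + np.argwhere(tumor) * vol.spacing_mm
    dists = cKDTree(tum_pts).query(pts, workers=-1)[0]

    apex = tum_pts.mean(axis=0)
    axis = np.array([0.0, 0.0, -1.0])       # deep = straight down
    e1 = np.array([0.0, 1.0, 0.0])          # anterior direction (+y) in base plane
    e2 = np.cross(axis, e1)
    hint = np.array([1.0, 0.0, 0.0])
    cm_plus = bool(hint @ e2 > 0)

    regions = np.array(
        [
            _classify_point_truth(p, apex, axis, e1, e2, 45.0, cm_plus)
            for p in pts
        ]
    )
    margins = {}
    for name in ("anterior", "posterior", "craniomedial", "caudolateral", "deep_central"):
        sel = regions == name
        margins[name] = float(dists[sel].min()) if sel.any() else None
    return {"margins": margins, "points": pts, "regions": regions}


def perturb_tumor_outline(
    tumor_mask: np.ndarray,
    spacing_mm,
    bias_mm: float,
    roughness_mm: float,
    seed: int,
    specimen_mask: Optional[np.ndarray] = None,
    correlation_mm: float = 5.0,
) -> np.ndarray:
    """Simulated observer outline: a smooth signed offset of the tumor surface.

    The tumor's signed distance field (positive outside) is thresholded at
    ``bias_mm`` plus a Gaussian-correlated noise field with standard
    deviation ``roughness_mm`` and correlation length ``correlation_mm``.
    Positive bias dilates (observer overestimation), negative bias erodes.
    The result is clipped to the specimen support when one is given.

    Raises ``TumorAnnihilatedError`` (carrying the smallest surviving bias)
    when the erosion removes every voxel.
    """
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    spacing_mm = np.broadcast_to(np.asarray(spacing_mm, dtype=float).ravel(), (3,)) \
        if np.size(spacing_mm) != 3 else np.asarray(spacing_mm, dtype=float)
    sd = ndimage.distance_transform_edt(~tumor_mask, sampling=spacing_mm) - \
        ndimage.distance_transform_edt(tumor_mask, sampling=spacing_mm)
    if roughness_mm > 0:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(tumor_mask.shape)
        noise = ndimage.gaussian_filter(noise, sigma=correlation_mm / spacing_mm)
        noise = noise / max(noise.std(), 1e-12) * roughness_mm
    else:
        noise = 0.0
    new = sd <= bias_mm + noise
    if specimen_mask is not None:
        new &= np.asarray(specimen_mask, dtype=bool)
    if not new.any():
        raise TumorAnnihilatedError(float(sd.min()))
    return new


def random_phantom_config(seed: int, spacing_mm: float = 0.3) -> PhantomConfig:
    """A randomized but always-valid phantom configuration.

    Samples specimen and tumor ellipsoids so that the tumor stays strictly
    interior while per-region margins spread over roughly 1.5-10 mm, giving
    cohorts a realistic mix of adequate and inadequate margins.
    """
    rng = np.random.default_rng(seed)
    ax = rng.uniform((11.0, 15.0, 9.0), (16.0, 22.0, 13.0))
    t_ax = rng.uniform(2.5, 0.42 * ax.min(), size=3)
    # offset the tumor, keeping it >1.5 mm clear of the surface
    room = ax - t_ax
    off = rng.uniform(-0.45, 0.45, size=3) * room
    # bias downward so deep margins are the tight ones, as in real specimens
    off[2] = -abs(off[2])
    scale = min(1.0, ((room - 1.5).clip(min=0.1) / np.maximum(np.abs(off), 1e-9)).min())
    off = off * min(scale, 1.0)
    return PhantomConfig(
        specimen_axes_mm=tuple(np.round(ax, 2)),
        tumor_center_mm=tuple(np.round(off, 2)),
        tumor_axes_mm=tuple(np.round(t_ax, 2)),
        spacing_mm=spacing_mm,
        seed=int(rng.integers(0, 2**31 - 1)),
        bumpiness_mm=float(np.round(rng.uniform(0.0, 0.6), 2)),
    )


def save_phantom(phantom: Phantom, directory) -> None:
    """Phantom as NIfTI label volume plus a JSON ground-truth sidecar."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    save_labeled_volume(phantom.volume, d / "phantom_labels.nii.gz")
    sidecar = {
        "config": asdict(phantom.config),
        "truth_margins_mm": phantom.truth_margins,
        "anterior_point_mm": phantom.anterior_point_mm.tolist(),
        "posterior_point_mm": phantom.posterior_point_mm.tolist(),
        "craniomedial_hint": phantom.craniomedial_hint.tolist(),
        "up_axis": phantom.up_axis.tolist(),
    }
    (d / "phantom_truth.json").write_text(json.dumps(sidecar, indent=2))
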