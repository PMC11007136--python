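"""Five-region anatomical partition of a specimen surface.

Pathology reports tongue-specimen margins at five locations: anterior,
posterior, craniomedial (toward the dorsum of the tongue), caudolateral
(toward the floor of mouth) and deep central (directly under the tumor).
The 3D analogue used here:

* a total-least-squares plane is fitted to the mucosa vertices; its normal,
  oriented into the specimen, is the "deep" direction;
* a cone (default half-angle 45 deg) with apex at the middle of the tumor
  and axis along the deep direction designates the deep central region;
* the remainder is split into four quadrants by azimuth about the cone
  axis, with +-45 deg sectors centered on the anterior and posterior
  directions, and the two side sectors named craniomedial / caudolateral
  according to a user-supplied hint vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConeGeometryError, MucosaFitError
from .specimen import DigitalSpecimen

REGIONS = ("anterior", "posterior", "craniomedial", "caudolateral", "deep_central")
REGION_CODES = {name: i for i, name in enumerate(REGIONS)}


@dataclass
class Plane:
    point_mm: np.ndarray
    unit_normal: np.ndarray

    def __post_init__(self):
        self.point_mm = np.asarray(self.point_mm, dtype=float).reshape(3)
        n = np.asarray(self.unit_normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ConeGeometryError("zero plane normal")
        self.unit_normal = n / norm

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(pts) - self.point_mm) @ self.unit_normal


@dataclass
class Cone:
    """One-sided infinite cone: apex, unit axis, half-angle in (0, 90) deg."""

    apex_mm: np.ndarray
    unit_axis: np.ndarray
    half_angle_deg: float = 45.0

    def __post_init__(self):
        self.apex_mm = np.asarray(self.apex_mm, dtype=float).reshape(3)
        a = np.asarray(self.unit_axis, dtype=float).reshape(3)
        norm = np.linalg.norm(a)
        if norm == 0:
            raise ConeGeometryError("zero cone axis")
        self.unit_axis = a / norm
        if not 0.0 < self.half_angle_deg < 90.0:
            raise ConeGeometryError(f"half angle {self.half_angle_deg} outside (0, 90)")

    def contains(self, pts: np.ndarray) -> np.ndarray:
        """Membership with the boundary tie-broken INTO the cone.

        A point belongs iff it lies on the axis-positive side and the angle
        between (p - apex) and the axis is <= half_angle.
        """
        v = np.atleast_2d(pts) - self.apex_mm
        proj = v @ self.unit_axis
        norms = np.linalg.norm(v, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.where(norms > 0, proj / norms, 1.0)
        return (proj > 0) & (cosang >= np.cos(np.deg2rad(self.half_angle_deg)) - 1e-12)


@dataclass
class RegionPartition:
    """Per-vertex region labels plus the generating geometry."""

    labels: np.ndarray                  # (n,) int codes into REGIONS
    plane: Plane
    cone: Cone
    anterior_point_mm: np.ndarray
    posterior_point_mm: np.ndarray
    craniomedial_hint: np.ndarray

    @property
    def names(self) -> np.ndarray:
        return np.asarray(REGIONS)[self.labels]

    def vertex_counts(self) -> dict:
        return {name: int(np.sum(self.labels == code)) for name, code in REGION_CODES.items()}


def fit_mucosa_plane(specimen: DigitalSpecimen) -> Plane:
    """Total-least-squares plane through the mucosa-flagged vertices.

    The normal (smallest principal direction of the vertex scatter) is
    oriented from the mucosa centroid toward the specimen interior, giving
    the deep direction.
    """
    pts = specimen.outer_surface.vertices[specimen.mucosa_vertex_flags]
    if len(pts) < 3:
        raise MucosaFitError(f"{len(pts)} mucosa vertices; need >= 3")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise MucosaFitError("mucosa vertices are collinear")
    normal = vt[2]
    interior = specimen.outer_surface.vertices.mean(axis=0)
    if np.dot(normal, interior - centroid) < 0:
        normal = -normal
    return Plane(point_mm=centroid, unit_normal=normal)


def build_deep_cone(
    specimen: DigitalSpecimen,
    plane: Plane,
    apex_override: Optional[np.ndarray] = None,
    half_angle_deg: float = 45.0,
) -> Cone:
    """Deep-central cone: apex in the middle of the tumor, axis along the
    deep-oriented mucosa-plane normal.

    The apex defaults to the tumor-support centroid (the reproducible proxy
    for manual placement); pass ``apex_override`` to mimic a manual choice.
    """
    apex = specimen.tumor_centroid_mm if apex_override is None else np.asarray(apex_override, float)
    return Cone(apex_mm=apex, unit_axis=plane.unit_normal, half_angle_deg=half_angle_deg)


def partition_surface(
    specimen: DigitalSpecimen,
    cone: Cone,
    anterior_point_mm: np.ndarray,
    posterior_point_mm: np.ndarray,
    craniomedial_hint: np.ndarray,
) -> RegionPartition:
    """Assign every outer-surface vertex to exactly one of the five regions.

    Vertices inside the cone (boundary included) are deep_central. The rest
    are classified by azimuth about the cone axis measured from the anterior
    direction (the projection of posterior->anterior onto the cone-base
    plane): [-45, 45) anterior, [135, 225) posterior, and the two remaining
    quadrants craniomedial / caudolateral, disambiguated by the projection
    of ``craniomedial_hint``. Half-open intervals make boundary azimuths
    deterministic.
    """
    ant = np.asarray(anterior_point_mm, dtype=float).reshape(3)
    post = np.asarray(posterior_point_mm, dtype=float).reshape(3)
    hint = np.asarray(craniomedial_hint, dtype=float).reshape(3)
    axis = cone.unit_axis

    ap = ant - post
    if np.linalg.norm(ap) < 1e-9:
        raise ConeGeometryError("anterior and posterior points coincide")
    e1 = ap - np.dot(ap, axis) * axis          # anterior direction in base plane
    if np.linalg.norm(e1) < 1e-9:
        raise ConeGeometryError("anterior-posterior direction parallel to cone axis")
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(axis, e1)                    # completes right-handed base frame

    h = hint - np.dot(hint, axis) * axis
    if np.linalg.norm(h) < 1e-9:
        raise ConeGeometryError("craniomedial hint parallel to cone axis")
    if abs(np.dot(h / np.linalg.norm(h), e2)) < 1e-9:
        raise ConeGeometryError("craniomedial hint parallel to the anterior-posterior direction")
    cm_is_plus_e2 = np.dot(h, e2) > 0

    verts = specimen.outer_surface.vertices
    labels = np.full(len(verts), -1, dtype=np.int8)
    inside = cone.contains(verts)
    labels[inside] = REGION_CODES["deep_central"]

    rest = ~inside
    v = verts[rest] - cone.apex_mm
    az = np.degrees(np.arctan2(v @ e2, v @ e1)) % 360.0
    quad = np.full(rest.sum(), -1, dtype=np.int8)
    quad[(az >= 315.0) | (az < 45.0)] = REGION_CODES["anterior"]
    quad[(az >= 135.0) & (az < 225.0)] = REGION_CODES["posterior"]
    plus = (az >= 45.0) & (az < 135.0)
    minus = (az >= 225.0) & (az < 315.0)
    cm, cl = REGION_CODES["craniomedial"], REGION_CODES["caudolateral"]
    quad[plus] = cm if cm_is_plus_e2 else cl
    quad[minus] = cl if cm_is_plus_e2 else cm
    labels[rest] = quad
    assert not np.any(labels < 0), "unlabeled vertex (unreachable)"

    plane = Plane(point_mm=cone.apex_mm, unit_normal=axis)
    return RegionPartition(
        labels=labels.astype(np.int64),
        plane=plane,
        cone=cone,
        anterior_point_mm=ant,
        posterior_point_mm=post,
        craniomedial_hint=hint,
    )
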