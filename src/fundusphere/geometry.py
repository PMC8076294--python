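"""Spherical eye-model geometry for ultra-widefield fundus images.

Ultra-widefield scanning-laser devices render the curved retina as a flat
2D raster, so distances, angles and areas read directly off the image are
distorted, increasingly so toward the far periphery.  This module models the
eye as a sphere whose **diameter equals the measured axial length** and maps
image pixels back onto that sphere by inverse stereographic ("reverse stereo")
projection.  All morphometry — geodesic distances, vertex angles, areas — is
then carried out on the sphere by spherical triangulation, on a globe sized
per eye rather than on a fixed 24-mm schematic eye.

Conventions
-----------
* Eye-centered right-handed frame: ``+z`` anterior pole, ``-z`` posterior
  pole (center of an on-axis fundus image), ``+y`` superior (image-up),
  ``+x`` temporal-in-image for a right eye (OD).
* Sphere points are unit 3-vectors (``numpy`` arrays, shape ``(..., 3)``).
* Pixels are 0-based ``(x, y)`` with origin at the top-left corner; image-up
  is decreasing ``y``.
* The projection plane is tangent at the posterior pole and the projection
  center is the anterior pole, which is the standard conformal choice: a
  point at polar angle ``theta`` from the posterior pole lands at plane
  radius ``rho = 2 R tan(theta / 2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GeometryError",
    "OutOfFieldError",
    "SingularityError",
    "DegenerateConfigurationError",
    "EyeModel",
    "FundusFrame",
    "GeodesicResult",
    "FIXED_AXIAL_LENGTH_MM",
    "as_unit_vectors",
    "reverse_project",
    "forward_project",
    "geodesic_distance",
    "spherical_angle",
    "spherical_area",
]

#: Axial length (mm) of the fixed schematic eye used by conventional 2D
#: analyzers; exposed so the uncorrected behavior can be reproduced.
FIXED_AXIAL_LENGTH_MM = 24.0

_UNIT_TOL = 1e-6  # renormalize within this, reject beyond


class GeometryError(ValueError):
    """Invalid geometric input."""


class OutOfFieldError(GeometryError):
    """Pixel lies outside the calibrated image circle."""


class SingularityError(GeometryError):
    """Projection undefined (anterior pole)."""


class DegenerateConfigurationError(GeometryError):
    """Coincident or antipodal points where a direction is required."""


@dataclass(frozen=True)
class EyeModel:
    """A per-eye sphere: diameter = axial length, assumed perfectly spherical.

    Parameters
    ----------
    axial_length_mm:
        Anteroposterior length of the eye in mm; the model sphere diameter.
    laterality:
        ``"OD"`` (right) or ``"OS"`` (left).
    check_range:
        When True (default), reject axial lengths outside [20, 27] mm; highly
        myopic eyes (> 27 mm, frequently staphylomatous) violate the
        spherical assumption and were excluded from the normative cohort.
    """

    axial_length_mm: float
    laterality: str = "OD"
    check_range: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.axial_length_mm) or self.axial_length_mm <= 0:
            raise GeometryError("axial length must be a positive finite length in mm")
        if self.laterality not in ("OD", "OS"):
            raise GeometryError(f"laterality must be 'OD' or 'OS', got {self.laterality!r}")
        if self.check_range and not (20.0 <= self.axial_length_mm <= 27.0):
            raise GeometryError(
                f"axial length {self.axial_length_mm} mm outside the accepted "
                "range [20, 27] mm; pass check_range=False to override"
            )

    @property
    def radius_mm(self) -> float:
        """Sphere radius in mm (half the axial length)."""
        return self.axial_length_mm / 2.0

    @classmethod
    def fixed(cls, laterality: str = "OD") -> "EyeModel":
        """The uncorrected 24-mm schematic eye (no axial-length adjustment)."""
        return cls(FIXED_AXIAL_LENGTH_MM, laterality)


@dataclass(frozen=True)
class FundusFrame:
    """Calibration of the 2D fundus raster.

    The image circle of radius ``min(width, height) / 2`` is assumed to span
    the device field of view: its rim corresponds to polar angle
    ``fov_deg / 2`` from the posterior pole.  The proprietary raster-scan
    optics of real devices are not modeled; this field-of-view-calibrated
    stereographic frame is a documented stand-in.

    ``mirror_os=True`` flips the horizontal axis for left eyes so that ``+x``
    remains the temporal direction on the sphere for either laterality.
    """

    width_px: int
    height_px: int
    center_px: tuple[float, float] | None = None
    fov_deg: float = 200.0
    mirror_os: bool = False

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise GeometryError("image dimensions must be positive")
        if not (0.0 < self.fov_deg < 360.0):
            raise GeometryError("fov_deg must lie in (0, 360)")
        if self.center_px is None:
            object.__setattr__(
                self,
                "center_px",
                ((self.width_px - 1) / 2.0, (self.height_px - 1) / 2.0),
            )

    @property
    def radius_px(self) -> float:
        """Radius of the calibrated image circle in pixels."""
        return min(self.width_px, self.height_px) / 2.0

    def plane_scale_px_per_mm(self, eye: EyeModel) -> float:
        """Pixels per mm on the tangent plane for a given eye.

        The rim of the image circle sits at plane radius
        ``2 R tan(fov / 4)`` mm, so the scale is the pixel radius divided by
        that length.
        """
        rho_rim = 2.0 * eye.radius_mm * np.tan(np.radians(self.fov_deg) / 4.0)
        return self.radius_px / rho_rim


@dataclass(frozen=True)
class GeodesicResult:
    """A great-circle separation: arc length in mm and central angle in rad."""

    distance_mm: np.ndarray | float
    central_angle_rad: np.ndarray | float


def as_unit_vectors(v, tol: float = _UNIT_TOL) -> np.ndarray:
    """Validate and renormalize sphere points of shape ``(..., 3)``.

    Norms within ``tol`` of 1 are renormalized; anything farther is rejected.
    """
    arr = np.asarray(v, dtype=float)
    if arr.shape[-1] != 3:
        raise GeometryError(f"sphere points must have 3 components, got shape {arr.shape}")
    norms = np.linalg.norm(arr, axis=-1)
    if np.any(~np.isfinite(norms)) or np.any(np.abs(norms - 1.0) > tol):
        raise GeometryError("input is not a unit vector (|norm - 1| exceeds tolerance)")
    return arr / norms[..., None]


def _plane_from_pixels(pixel, frame: FundusFrame, eye: EyeModel):
    """Pixel coords -> tangent-plane coords (u temporal, v superior) in mm."""
    px = np.asarray(pixel, dtype=float)
    if px.shape[-1] != 2:
        raise GeometryError(f"pixels must have 2 components, got shape {px.shape}")
    cx, cy = frame.center_px
    dx = px[..., 0] - cx
    dy = cy - px[..., 1]  # image-up is superior
    r_px = np.hypot(dx, dy)
    if np.any(r_px > frame.radius_px * (1.0 + 1e-9)):
        raise OutOfFieldError("pixel outside the calibrated image circle")
    scale = frame.plane_scale_px_per_mm(eye)
    u = dx / scale
    v = dy / scale
    if frame.mirror_os and eye.laterality == "OS":
        u = -u
    return u, v


def reverse_project(pixel, frame: FundusFrame, eye: EyeModel) -> np.ndarray:
    """Map image pixels onto the eye sphere (inverse stereographic projection).

    Accepts a single ``(x, y)`` pair or an array of shape ``(..., 2)``;
    returns unit vectors of shape ``(..., 3)``.  The image center maps to the
    posterior pole ``(0, 0, -1)``.

    Raises
    ------
    OutOfFieldError
        If any pixel lies outside the calibrated image circle.
    """
    u, v = _plane_from_pixels(pixel, frame, eye)
    two_r = 2.0 * eye.radius_mm
    rho2 = u * u + v * v
    denom = two_r * two_r + rho2
    k = 2.0 * two_r / denom  # sin(theta) / rho, finite at rho = 0
    x = u * k
    y = v * k
    z = -(two_r * two_r - rho2) / denom  # -cos(theta)
    return np.stack([x, y, z], axis=-1)


def forward_project(point, frame: FundusFrame, eye: EyeModel) -> np.ndarray:
    """Map sphere points to image pixels; exact inverse of :func:`reverse_project`.

    Raises
    ------
    SingularityError
        If a point is at (or numerically at) the anterior pole, where the
        stereographic projection has no image.
    """
    p = as_unit_vectors(point)
    z = p[..., 2]
    denom = 1.0 - z  # = 1 + cos(theta)
    if np.any(denom < 1e-12):
        raise SingularityError("anterior pole has no stereographic image")
    two_r = 2.0 * eye.radius_mm
    u = two_r * p[..., 0] / denom
    v = two_r * p[..., 1] / denom
    if frame.mirror_os and eye.laterality == "OS":
        u = -u
    scale = frame.plane_scale_px_per_mm(eye)
    cx, cy = frame.center_px
    px = cx + u * scale
    py = cy - v * scale
    return np.stack([px, py], axis=-1)


def geodesic_distance(p, q, eye: EyeModel) -> GeodesicResult:
    """Great-circle distance between sphere points, scaled by the eye radius.

    Uses the two-argument arctangent form ``atan2(|p x q|, p . q)``, which is
    numerically stable for nearly coincident and nearly antipodal points.
    Symmetric in ``p`` and ``q``; broadcasts over leading dimensions.
    """
    pu = as_unit_vectors(p)
    qu = as_unit_vectors(q)
    cross = np.cross(pu, qu)
    angle = np.arctan2(np.linalg.norm(cross, axis=-1), np.sum(pu * qu, axis=-1))
    if angle.ndim == 0:
        angle = float(angle)
    return GeodesicResult(distance_mm=eye.radius_mm * angle, central_angle_rad=angle)


def _tangent_toward(vertex: np.ndarray, target: np.ndarray, min_angle_rad: float) -> np.ndarray:
    """Unit tangent at ``vertex`` along the great circle toward ``target``."""
    proj = target - np.sum(target * vertex, axis=-1, keepdims=True) * vertex
    norm = np.linalg.norm(proj, axis=-1, keepdims=True)
    # norm = sin(central angle); reject (near-)coincident or antipodal targets
    if np.any(norm < np.sin(min_angle_rad)):
        raise DegenerateConfigurationError(
            "vertex coincident with (or antipodal to) a target point; "
            "the tangent direction is undefined"
        )
    return proj / norm


def spherical_angle(vertex, a, c, signed: bool = False, min_angle_deg: float = 1e-6) -> np.ndarray | float:
    """Angle at ``vertex`` between the great-circle arcs toward ``a`` and ``c``.

    Returns degrees in ``[0, 180]``, or a signed value in ``(-180, 180]`` when
    ``signed=True``.  The signed convention treats the arc toward ``a`` as the
    reference direction; rotating it toward image-up/superior is positive
    (i.e. positive sign when the swept direction has a ``+y`` component for a
    vertex near the posterior pole, matching how the fundus is viewed).

    Broadcasts: ``vertex``/``a`` may be single points while ``c`` is an array.
    """
    v = as_unit_vectors(vertex)
    pa = as_unit_vectors(a)
    pc = as_unit_vectors(c)
    v, pa, pc = np.broadcast_arrays(v, pa, pc)
    min_rad = np.radians(max(min_angle_deg, 1e-12))
    ta = _tangent_toward(v, pa, min_rad)
    tc = _tangent_toward(v, pc, min_rad)
    cross = np.cross(ta, tc)
    ang = np.degrees(np.arctan2(np.linalg.norm(cross, axis=-1), np.sum(ta * tc, axis=-1)))
    if signed:
        # orientation as seen on the fundus image: normal is the inward -v
        orient = np.sum(cross * (-v), axis=-1)
        sign = np.where(orient < 0.0, -1.0, 1.0)
        ang = ang * sign
    if ang.ndim == 0:
        return float(ang)
    return ang


def _triangle_solid_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Signed solid angle of spherical triangle (a, b, c) (Van Oosterom-Strackee)."""
    num = np.dot(a, np.cross(b, c))
    den = 1.0 + np.dot(a, b) + np.dot(b, c) + np.dot(c, a)
    return 2.0 * np.arctan2(num, den)


def spherical_area(polygon: Sequence, eye: EyeModel) -> float:
    """Area (mm^2) of a simple spherical polygon given as ordered vertices.

    Computed as the absolute sum of signed fan-triangle solid angles times
    R^2; exact for simple (non-self-intersecting) polygons regardless of
    orientation.

    Raises
    ------
    GeometryError
        Fewer than 3 vertices, repeated adjacent vertices, or antipodal
        adjacent vertices.
    """
    pts = as_unit_vectors(np.asarray(polygon, dtype=float))
    if pts.ndim != 2 or len(pts) < 3:
        raise GeometryError("a spherical polygon needs at least 3 vertices")
    nxt = np.roll(pts, -1, axis=0)
    dots = np.sum(pts * nxt, axis=-1)
    if np.any(dots > 1.0 - 1e-12):
        raise GeometryError("repeated adjacent vertices in spherical polygon")
    if np.any(dots < -1.0 + 1e-12):
        raise GeometryError("antipodal adjacent vertices: the connecting arc is ambiguous")
    total = 0.0
    for i in range(1, len(pts) - 1):
        total += _triangle_solid_angle(pts[0], pts[i], pts[i + 1])
    area = abs(total) * eye.radius_mm**2
    if area <= 0.0:
        raise GeometryError("degenerate polygon with zero spherical area")
    return area
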