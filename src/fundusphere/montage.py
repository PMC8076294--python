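"""Registration of multi-gaze ultra-widefield views into one spherical map.

A single on-axis capture misses the far periphery, so two additional views
are taken with the subject fixating up and down.  Because a change of gaze
is (to good approximation) a pure rotation of the globe, the three views are
related by 3D rotations on the model sphere.  Each off-axis view is paired
with the on-axis view through six manually marked correspondences — the
optic disc plus five vascular bifurcations, one per fundus region — giving
twelve alignment points per montage.  The rotation is recovered from the
reverse-projected landmarks by solving the orthogonal-Procrustes (Wahba)
problem; a 2D affine fit on the raw pixels is kept as a comparison path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .geometry import (
    EyeModel,
    FundusFrame,
    GeometryError,
    forward_project,
    reverse_project,
)

__all__ = [
    "GAZES",
    "UnderdeterminedError",
    "GazeView",
    "LandmarkPair",
    "LandmarkCorrespondence",
    "RegionPartition",
    "partition_regions",
    "gaze_rotation_matrix",
    "estimate_view_rotation",
    "estimate_affine_2d",
    "transfer_points",
    "SphericalComposite",
    "compose_montage",
]

GAZES = ("on_axis", "up", "down")

#: Auxiliary-line directions (degrees from the image horizontal) bounding the
#: five fundus regions used to pick one vascular bifurcation each.
AUXILIARY_ANGLES_DEG = (-10.0, 30.0, 70.0, 110.0, 150.0, 190.0)


class UnderdeterminedError(GeometryError):
    """Too few or degenerate correspondences to estimate a rotation."""


@dataclass
class GazeView:
    """One capture: gaze direction plus (optionally) its raster image."""

    gaze: str
    image: np.ndarray | None = None
    nominal_gaze_rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.gaze not in GAZES:
            raise ValueError(f"gaze must be one of {GAZES}, got {self.gaze!r}")


@dataclass(frozen=True)
class LandmarkPair:
    role: str  # "optic_disc" | "vascular_bifurcation"
    region_id: int | None
    pixel_on: tuple[float, float]
    pixel_off: tuple[float, float]


@dataclass
class LandmarkCorrespondence:
    """Point pairs between the on-axis view and one off-axis view."""

    off_gaze: str
    points: list[LandmarkPair]

    def pixel_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        on = np.array([p.pixel_on for p in self.points], dtype=float)
        off = np.array([p.pixel_off for p in self.points], dtype=float)
        return on, off


@dataclass(frozen=True)
class RegionPartition:
    """Five 40-degree wedges around a center point.

    Wedge ``k`` (1..5) covers image-direction angles in
    ``[-10 + 40 (k - 1), -10 + 40 k)`` degrees, measured counterclockwise
    from the horizontal (+x, image-up positive); pixels whose direction falls
    outside ``[-10, 190)`` get label 0.
    """

    center_px: tuple[float, float]
    auxiliary_angles_deg: tuple[float, ...] = AUXILIARY_ANGLES_DEG

    def region_of(self, pixels) -> np.ndarray:
        px = np.asarray(pixels, dtype=float)
        scalar = px.ndim == 1
        cx, cy = self.center_px
        ang = np.degrees(np.arctan2(cy - px[..., 1], px[..., 0] - cx))
        start = self.auxiliary_angles_deg[0]
        shifted = np.mod(ang - start, 360.0)
        # snap floating noise at wedge boundaries toward the lower-closed edge
        k = np.floor((shifted + 1e-9) / 40.0).astype(int) + 1
        labels = np.where(k <= 5, k, 0)
        return int(labels) if scalar else labels

    def label_map(self, frame: FundusFrame) -> np.ndarray:
        """Per-pixel region labels for a whole frame (0 outside the wedges)."""
        xs, ys = np.meshgrid(np.arange(frame.width_px), np.arange(frame.height_px))
        return self.region_of(np.stack([xs, ys], axis=-1))


def partition_regions(frame: FundusFrame, center: tuple[float, float] | None = None) -> RegionPartition:
    """Build the five-region partition around ``center`` (default: frame center)."""
    c = tuple(frame.center_px) if center is None else (float(center[0]), float(center[1]))
    if not (0 <= c[0] < frame.width_px and 0 <= c[1] < frame.height_px):
        raise GeometryError("partition center must lie inside the image")
    return RegionPartition(center_px=c)


def gaze_rotation_matrix(gaze: str, angle_deg: float = 35.0) -> np.ndarray:
    """Nominal view->on-axis rotation for an up/down gaze about the horizontal axis.

    For an up gaze the view center maps to a point with a superior (+y)
    component in the on-axis frame.  Used only to initialize or sanity-check;
    the working estimate always comes from landmarks.
    """
    if gaze == "on_axis":
        return np.eye(3)
    if gaze not in GAZES:
        raise ValueError(f"unknown gaze {gaze!r}")
    a = np.radians(angle_deg if gaze == "up" else -angle_deg)
    ca, sa = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, ca, -sa], [0.0, sa, ca]])


def estimate_view_rotation(
    corr: LandmarkCorrespondence, frame: FundusFrame, eye: EyeModel
) -> np.ndarray:
    """Rotation taking off-axis sphere points onto their on-axis mates.

    Reverse-projects both pixel sets and solves the Wahba problem: the proper
    rotation ``R`` minimizing ``sum |R p_off - p_on|^2``, via SVD of the
    correlation matrix (Kabsch), with the determinant corrected to +1.

    Raises
    ------
    UnderdeterminedError
        Fewer than two correspondences, or all directions mutually parallel
        (a rotation about the common axis would be unconstrained).
    """
    pix_on, pix_off = corr.pixel_arrays()
    if len(pix_on) < 2:
        raise UnderdeterminedError("need at least 2 correspondences to estimate a rotation")
    p_on = reverse_project(pix_on, frame, eye)
    p_off = reverse_project(pix_off, frame, eye)
    crosses = np.linalg.norm(np.cross(p_off[0], p_off[1:]), axis=-1)
    if np.all(crosses < 1e-8):
        raise UnderdeterminedError("all landmark directions are parallel; rotation is underdetermined")
    b = p_on.T @ p_off
    u, _, vt = np.linalg.svd(b)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


def estimate_affine_2d(corr: LandmarkCorrespondence) -> np.ndarray:
    """Least-squares 2D affine map (2x3) from off-axis to on-axis pixels.

    Comparison path for registration done directly in the image domain; the
    spherical rotation is the physically motivated default.
    """
    pix_on, pix_off = corr.pixel_arrays()
    if len(pix_on) < 3:
        raise UnderdeterminedError("need at least 3 correspondences for an affine fit")
    design = np.hstack([pix_off, np.ones((len(pix_off), 1))])
    coef, *_ = np.linalg.lstsq(design, pix_on, rcond=None)
    return coef.T  # (2, 3)


def transfer_points(points_view, rotation: np.ndarray) -> np.ndarray:
    """Rotate view-frame sphere points into the on-axis frame."""
    return np.asarray(points_view, dtype=float) @ np.asarray(rotation, dtype=float).T


@dataclass
class SphericalComposite:
    """Equirectangular composite: colatitude x longitude intensity + source map.

    ``colat_deg[i]`` is the polar angle from the posterior pole of row ``i``;
    ``lon_deg[j]`` the azimuth of column ``j``.  ``source`` holds the index of
    the contributing view (-1 where no view covers the bin).
    """

    colat_deg: np.ndarray
    lon_deg: np.ndarray
    intensity: np.ndarray
    source: np.ndarray
    view_gazes: list[str]

    def coverage(self) -> np.ndarray:
        return self.source >= 0


def compose_montage(
    views: Sequence[GazeView],
    rotations: Mapping[str, np.ndarray],
    frame: FundusFrame,
    eye: EyeModel,
    bin_deg: float = 0.1,
    max_colat_deg: float = 180.0,
    visible_fov_deg: float | None = None,
) -> SphericalComposite:
    """Fuse views into a single spherical map in the on-axis frame.

    Every composite bin direction is pulled back into each view (inverse
    rotation + forward projection) and sampled by nearest neighbor.  Where
    views overlap the one whose own center is geodesically closest wins — no
    feathering, so downstream measurements never read interpolated seams.
    Views without a raster still contribute to the coverage/source maps.
    """
    gazes = [v.gaze for v in views]
    if gazes.count("on_axis") != 1:
        raise ValueError("exactly one on-axis view is required")
    for g in gazes:
        if g != "on_axis" and g not in rotations:
            raise ValueError(f"missing rotation for off-axis view {g!r}")

    half_fov = np.radians(min(frame.fov_deg, visible_fov_deg or frame.fov_deg) / 2.0)
    n_lat = max(2, int(round(max_colat_deg / bin_deg)))
    n_lon = max(4, int(round(360.0 / bin_deg)))
    colat = (np.arange(n_lat) + 0.5) * (max_colat_deg / n_lat)
    lon = -180.0 + (np.arange(n_lon) + 0.5) * (360.0 / n_lon)
    th = np.radians(colat)[:, None]
    ph = np.radians(lon)[None, :]
    dirs = np.stack(
        [
            np.broadcast_to(np.sin(th) * np.cos(ph), (n_lat, n_lon)),
            np.broadcast_to(np.sin(th) * np.sin(ph), (n_lat, n_lon)),
            np.broadcast_to(-np.cos(th), (n_lat, n_lon)),
        ],
        axis=-1,
    ).reshape(-1, 3)

    best = np.full(len(dirs), np.inf)
    intensity = np.full(len(dirs), np.nan)
    source = np.full(len(dirs), -1, dtype=np.int16)

    for idx, view in enumerate(views):
        rot = np.eye(3) if view.gaze == "on_axis" else np.asarray(rotations[view.gaze])
        p_view = dirs @ rot  # rows are R^T p
        theta_v = np.arccos(np.clip(-p_view[:, 2], -1.0, 1.0))
        in_field = theta_v < half_fov
        if not np.any(in_field):
            continue
        px = forward_project(p_view[in_field], frame, eye)
        ix = np.rint(px[:, 0]).astype(int)
        iy = np.rint(px[:, 1]).astype(int)
        ok = (ix >= 0) & (ix < frame.width_px) & (iy >= 0) & (iy < frame.height_px)
        cand = np.flatnonzero(in_field)[ok]
        score = theta_v[cand]
        win = score < best[cand]
        cand = cand[win]
        if cand.size == 0:
            continue
        best[cand] = theta_v[cand]
        source[cand] = idx
        if view.image is not None:
            img = np.asarray(view.image, dtype=float)
            if img.ndim == 3:  # long-wavelength (choroid-dominant) channel
                img = img[..., 0]
            intensity[cand] = img[iy[ok][win], ix[ok][win]]

    return SphericalComposite(
        colat_deg=colat,
        lon_deg=lon,
        intensity=intensity.reshape(n_lat, n_lon),
        source=source.reshape(n_lat, n_lon),
        view_gazes=gazes,
    )
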