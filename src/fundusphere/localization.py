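"""Vortex-vein-ampulla localization and fundus sectorization.

The ampulla center is not a well-defined image feature on its own; graders
instead draw straight lines through the thicker veins flowing into it, and
the center is taken as the common intersection of those lines.  With more
than two lines the intersection is overdetermined and is computed as the
least-squares point minimizing the summed squared perpendicular distances.

Sectors follow the clinical convention: the great circle through fovea and
optic-disc center is the horizontal axis, its perpendicular through the disc
the vertical axis, dividing the fundus into upper/lower lateral (temporal,
the fovea side) and upper/lower nasal quadrants — UL, LL, UN, LN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import (
    DegenerateConfigurationError,
    EyeModel,
    GeometryError,
    as_unit_vectors,
    geodesic_distance,
    spherical_angle,
)

__all__ = [
    "SECTORS",
    "NoIntersectionError",
    "VesselLine",
    "FundusAxes",
    "Ampulla",
    "intersect_vessel_lines",
    "signed_disc_angle",
    "assign_sector",
    "count_by_sector",
]

SECTORS = ("UL", "LL", "UN", "LN")

_PARALLEL_TOL_DEG = 0.5


class NoIntersectionError(ValueError):
    """All inflowing-vessel lines are (near-)parallel."""


@dataclass(frozen=True)
class VesselLine:
    """A straight line through an inflowing vessel, in image coordinates."""

    anchor: tuple[float, float]
    direction: tuple[float, float]
    ampulla_id: int | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise ValueError("vessel line direction must be non-zero")
        object.__setattr__(self, "direction", tuple(d / n))


@dataclass(frozen=True)
class FundusAxes:
    """Fovea and disc-center sphere points defining the sector axes."""

    fovea: np.ndarray
    disc_center: np.ndarray

    def __post_init__(self) -> None:
        f = as_unit_vectors(self.fovea)
        d = as_unit_vectors(self.disc_center)
        object.__setattr__(self, "fovea", f)
        object.__setattr__(self, "disc_center", d)
        sep = np.degrees(np.arctan2(np.linalg.norm(np.cross(f, d)), float(np.dot(f, d))))
        if sep <= 1.0:
            raise GeometryError("fovea and disc center must be separated by more than 1 degree")


@dataclass(frozen=True)
class Ampulla:
    """A localized vortex-vein ampulla."""

    center: np.ndarray
    sector: str
    eye_id: str = "eye"
    source_lines: tuple[VesselLine, ...] = ()


def intersect_vessel_lines(lines: Sequence[VesselLine]) -> np.ndarray:
    """Least-squares intersection of >= 2 vessel lines (ampulla center, px).

    Minimizes the sum of squared perpendicular distances to all lines via the
    closed-form normal equations; for exactly two non-parallel lines this is
    their exact intersection.

    Raises
    ------
    NoIntersectionError
        If fewer than two lines are given or all pairs are parallel within
        0.5 degrees.
    """
    if len(lines) < 2:
        raise NoIntersectionError("need at least 2 vessel lines")
    dirs = np.array([ln.direction for ln in lines], dtype=float)
    anchors = np.array([ln.anchor for ln in lines], dtype=float)
    sin_tol = np.sin(np.radians(_PARALLEL_TOL_DEG))
    cross = np.abs(dirs[:, None, 0] * dirs[None, :, 1] - dirs[:, None, 1] * dirs[None, :, 0])
    if np.all(cross < sin_tol):
        raise NoIntersectionError("all lines parallel within 0.5 degrees; no intersection")
    # A = sum(I - d d^T), b = sum((I - d d^T) a)
    proj = np.eye(2)[None, :, :] - dirs[:, :, None] * dirs[:, None, :]
    a_mat = proj.sum(axis=0)
    b_vec = np.einsum("nij,nj->i", proj, anchors)
    return np.linalg.solve(a_mat, b_vec)


def signed_disc_angle(center, axes: FundusAxes) -> np.ndarray | float:
    """Signed spherical angle at the disc from the disc->fovea direction.

    Positive toward superior; range ``(-180, 180]`` degrees.  Vectorized over
    an array of centers.
    """
    return spherical_angle(axes.disc_center, axes.fovea, center, signed=True)


def assign_sector(center, axes: FundusAxes, eye: EyeModel | None = None) -> np.ndarray | str:
    """Quadrant label (UL/LL/UN/LN) of an ampulla center.

    The signed disc angle ``a`` maps to sectors with half-open boundaries:
    ``[0, 90) -> UL``, ``(-90, 0) -> LL``, ``[90, 180] -> UN``,
    ``(-180, -90] -> LN``.  Lateral (temporal) is the fovea side.  The label
    depends only on the two axes, so it is invariant to axial length; ``eye``
    is accepted for interface symmetry.

    Raises
    ------
    DegenerateConfigurationError
        If a center coincides with the disc.
    """
    a = np.asarray(signed_disc_angle(center, axes))
    sector = np.where(
        (a >= 0.0) & (a < 90.0),
        "UL",
        np.where(a >= 90.0, "UN", np.where(a > -90.0, "LL", "LN")),
    )
    if sector.ndim == 0:
        return str(sector)
    return sector


def count_by_sector(sectors: Sequence[str]) -> dict[str, int]:
    """Quadrant, half-fundus and total ampulla counts for one eye.

    Half counts are consistent by construction:
    ``temporal + nasal = superior + inferior = total``.
    """
    arr = np.asarray(sectors, dtype=object)
    counts = {s: int(np.sum(arr == s)) for s in SECTORS}
    counts["total"] = int(arr.size)
    counts["temporal"] = counts["UL"] + counts["LL"]
    counts["nasal"] = counts["UN"] + counts["LN"]
    counts["superior"] = counts["UL"] + counts["UN"]
    counts["inferior"] = counts["LL"] + counts["LN"]
    return counts
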