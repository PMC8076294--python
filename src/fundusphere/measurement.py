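"""Per-eye quantification of vortex-vein-ampulla geometry.

For each ampulla this module reports the geodesic disc-to-ampulla distance
in mm (on the axial-length-sized sphere) and the fovea/disc/ampulla vertex
angle in degrees, then aggregates rows per sector and per eye.  Two angle
conventions circulate for this measurement — vertex at the optic disc
(fovea–disc–ampulla) and vertex at the ampulla (fovea–ampulla–disc); the
disc vertex is the default, as it is the angle the sectorization is built
on, and the ampulla vertex is exposed as a named variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import EyeModel, geodesic_distance, spherical_angle
from .localization import SECTORS, FundusAxes, assign_sector, count_by_sector

__all__ = [
    "EyeMeasurements",
    "disc_to_ampulla_distance",
    "disc_vertex_angle",
    "ampulla_vertex_angle",
    "summarize_eye",
    "cohort_table",
]

#: Covariate columns carried through to the measurement tables.
COVARIATES = ("age_yr", "sex", "bcva_logmar", "es_diopters", "axial_length_mm")


def disc_to_ampulla_distance(center, axes: FundusAxes, eye: EyeModel) -> np.ndarray | float:
    """Geodesic distance (mm) from the optic-disc center to an ampulla."""
    return geodesic_distance(axes.disc_center, center, eye).distance_mm


def disc_vertex_angle(center, axes: FundusAxes, signed: bool = False) -> np.ndarray | float:
    """Fovea–disc–ampulla angle (deg), vertex at the optic disc.

    The signed version (positive superior) is the quantity sectors are
    assigned from.  Invariant to axial length.
    """
    return spherical_angle(axes.disc_center, axes.fovea, center, signed=signed)


def ampulla_vertex_angle(center, axes: FundusAxes) -> np.ndarray | float:
    """Fovea–ampulla–disc angle (deg), vertex at the ampulla (variant reading)."""
    return spherical_angle(center, axes.fovea, axes.disc_center)


@dataclass
class EyeMeasurements:
    """Measurement table and summaries for one eye.

    ``table`` has one row per ampulla (sector, distance_mm, angle_deg plus
    covariates).  Sector means are means over member rows only; empty sectors
    are reported as NaN, never as zero.
    """

    eye_id: str
    table: pd.DataFrame
    counts: dict[str, int]
    sector_mean_distance_mm: dict[str, float]
    mean_distance_mm: float
    covariates: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def summarize_eye(
    centers,
    axes: FundusAxes,
    eye: EyeModel,
    eye_id: str = "eye",
    covariates: Mapping | None = None,
    angle_vertex: str = "disc",
) -> EyeMeasurements:
    """Measure all ampullae of one eye and aggregate.

    Parameters
    ----------
    centers:
        Array of ampulla sphere points, shape ``(n, 3)`` (``n`` may be 0).
    angle_vertex:
        ``"disc"`` (default) or ``"ampulla"``; which vertex the reported
        angle uses.
    """
    centers = np.asarray(centers, dtype=float).reshape(-1, 3)
    cov = dict(covariates or {})
    cov.setdefault("axial_length_mm", eye.axial_length_mm)
    n = len(centers)
    if n:
        sectors = np.atleast_1d(assign_sector(centers, axes))
        dist = np.atleast_1d(disc_to_ampulla_distance(centers, axes, eye))
        if angle_vertex == "disc":
            ang = np.atleast_1d(disc_vertex_angle(centers, axes))
        elif angle_vertex == "ampulla":
            ang = np.atleast_1d(ampulla_vertex_angle(centers, axes))
        else:
            raise ValueError("angle_vertex must be 'disc' or 'ampulla'")
    else:
        sectors = np.array([], dtype=object)
        dist = np.array([])
        ang = np.array([])

    table = pd.DataFrame(
        {
            "eye_id": eye_id,
            "ampulla_id": np.arange(n),
            "sector": sectors,
            "distance_mm": dist,
            "angle_deg": ang,
        }
    )
    for key in COVARIATES:
        if key in cov:
            table[key] = cov[key]

    counts = count_by_sector(sectors)
    sector_means = {
        s: float(dist[sectors == s].mean()) if counts[s] else float("nan") for s in SECTORS
    }
    return EyeMeasurements(
        eye_id=eye_id,
        table=table,
        counts=counts,
        sector_mean_distance_mm=sector_means,
        mean_distance_mm=float(dist.mean()) if n else float("nan"),
        covariates=cov,
    )


def cohort_table(measurements: Sequence[EyeMeasurements]) -> pd.DataFrame:
    """One row per eye: sector counts, sector mean distances, covariates.

    This is the input format of the statistics stage.
    """
    rows = []
    for m in measurements:
        row: dict = {"eye_id": m.eye_id, "n_total": m.counts["total"]}
        for s in SECTORS:
            row[f"n_{s}"] = m.counts[s]
            row[f"dist_{s}"] = m.sector_mean_distance_mm[s]
        row["mean_distance_mm"] = m.mean_distance_mm
        for key in COVARIATES:
            if key in m.covariates:
                row[key] = m.covariates[key]
        rows.append(row)
    df = pd.DataFrame(rows)
    if df["eye_id"].duplicated().any():
        raise ValueError("duplicated eye ids in cohort")
    return df
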