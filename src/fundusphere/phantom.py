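"""Synthetic cohort generator with full geometric ground truth.

No real ultra-widefield images of the normative cohort are available, so
every pipeline stage is exercised against phantoms: simulated eyes whose
axial lengths, per-quadrant ampulla counts and disc-to-ampulla distances are
drawn from the normative distributions, placed exactly on the model sphere,
and forward-rendered into per-view annotations (and optionally rasters) in
the same formats the measurement pipeline consumes.  Because generation and
measurement share the projection model, a noiseless phantom must be
recovered exactly — the identifiability property the test suite leans on.

Defaults encode the normative study conditions: axial length
N(24.92, 1.11^2) mm truncated to [22.47, 26.97]; quadrant ampulla counts as
rounded truncated normals with by-sex means 2.00/2.19/2.30/1.95 (men) and
1.68/2.05/2.08/1.95 (women) — averaging to 1.84/2.12/2.19/1.95 overall and
8.10/eye in a balanced cohort; quadrant distance means 14.04/15.55/13.29/
13.66 mm with SDs 1.12/1.31/1.03/1.20.  Per-eye distance means shift with
axial length (larger globes carry their ampullae farther from the disc) at
0.37 mm per mm of axial length, with residual spread shrunk so the marginal
quadrant SDs keep their nominal values.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .geometry import EyeModel, FundusFrame, forward_project
from .localization import SECTORS, FundusAxes, assign_sector
from .montage import gaze_rotation_matrix

__all__ = ["PhantomConfig", "PhantomTruth", "generate_cohort", "eye_annotations", "degrade", "render_views"]


def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions of the simulated normative cohort.

    Quadrant-ordered tuples follow ``(UL, LL, UN, LN)``.  All lengths in mm,
    angles in degrees, pixel quantities in px.  The seed fully determines the
    generated cohort.
    """

    n_eyes: int = 74
    male_fraction: float = 0.5
    seed: int = 0

    # demographics
    axial_length_mean_mm: float = 24.92
    axial_length_sd_mm: float = 1.11
    axial_length_bounds_mm: tuple[float, float] = (22.47, 26.97)
    age_mean_yr: float = 36.53
    age_sd_yr: float = 10.13
    age_bounds_yr: tuple[float, float] = (20.0, 55.0)
    bcva_mean_logmar: float = -0.22
    bcva_sd_logmar: float = 0.08
    es_mean_diopters: float = -3.26
    es_sd_diopters: float = 2.62
    es_bounds_diopters: tuple[float, float] = (-9.63, -0.75)

    # ampulla counts: rounded truncated normals, by sex
    count_means_male: tuple[float, ...] = (2.00, 2.19, 2.30, 1.95)
    count_sds_male: tuple[float, ...] = (0.67, 0.57, 0.66, 0.40)
    count_means_female: tuple[float, ...] = (1.68, 2.05, 2.08, 1.95)
    count_sds_female: tuple[float, ...] = (0.63, 0.70, 0.76, 0.70)

    # disc-to-ampulla distances
    distance_means_mm: tuple[float, ...] = (14.04, 15.55, 13.29, 13.66)
    distance_sds_mm: tuple[float, ...] = (1.12, 1.31, 1.03, 1.20)
    distance_al_slope_mm_per_mm: float = 0.37
    min_distance_mm: float = 5.0

    # canonical geometry and imaging
    disc_nasal_deg: float = 15.0
    gaze_rotation_deg: float = 35.0
    fov_deg: float = 200.0
    visible_fov_deg: float = 140.0  # gradeable on-axis field (full angle)
    image_size_px: int = 1000
    laterality: str = "OD"

    # annotation degradation
    landmark_noise_px: float = 0.0
    missing_rate: float = 0.0

    @property
    def count_means_overall(self) -> tuple[float, ...]:
        return tuple(
            (m + f) / 2.0 for m, f in zip(self.count_means_male, self.count_means_female)
        )


@dataclass
class PhantomTruth:
    """Ground truth of a generated cohort.

    ``eyes`` holds one row per eye (demographics); ``ampullae`` one row per
    ampulla with the true sphere point, quadrant, geodesic disc distance and
    signed disc angle, plus visibility bookkeeping (best view, on-axis
    gradeability).  The disc/fovea sphere points and the nominal gaze
    rotations are shared across eyes.
    """

    config: PhantomConfig
    disc: np.ndarray
    fovea: np.ndarray
    eyes: pd.DataFrame
    ampullae: pd.DataFrame
    rotations: dict[str, np.ndarray]

    def eye_model(self, eye_id: str) -> EyeModel:
        al = float(self.eyes.set_index("eye_id").loc[eye_id, "axial_length_mm"])
        return EyeModel(al, self.config.laterality)

    def frame(self) -> FundusFrame:
        s = self.config.image_size_px
        return FundusFrame(s, s, fov_deg=self.config.fov_deg)

    def axes(self) -> FundusAxes:
        return FundusAxes(fovea=self.fovea, disc_center=self.disc)


def _canonical_axes(disc_nasal_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Fovea at the posterior pole; disc rotated nasally (-x for OD)."""
    d = np.radians(disc_nasal_deg)
    fovea = np.array([0.0, 0.0, -1.0])
    disc = np.array([-np.sin(d), 0.0, -np.cos(d)])
    return fovea, disc


def generate_cohort(config: PhantomConfig = PhantomConfig(), seed: int | None = None) -> PhantomTruth:
    """Draw a full cohort; deterministic given (config, seed).

    Ampulla placement: the quadrant is drawn from the count model, the
    azimuth uniformly within the quadrant's signed-disc-angle range, and the
    polar position chosen so the true geodesic disc distance follows the
    quadrant's distance distribution (redrawn while outside
    ``(min_distance_mm, pi R)``).  Truth sector labels therefore coincide
    with :func:`fundusphere.localization.assign_sector` by construction.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_eyes
    fovea, disc = _canonical_axes(cfg.disc_nasal_deg)

    n_male = int(round(n * cfg.male_fraction))
    sex = np.array(["M"] * n_male + ["F"] * (n - n_male), dtype=object)
    rng.shuffle(sex)
    is_male = sex == "M"

    al = _truncated_normal(
        rng, cfg.axial_length_mean_mm, cfg.axial_length_sd_mm, *cfg.axial_length_bounds_mm, size=n
    )
    age = _truncated_normal(rng, cfg.age_mean_yr, cfg.age_sd_yr, *cfg.age_bounds_yr, size=n)
    bcva = rng.normal(cfg.bcva_mean_logmar, cfg.bcva_sd_logmar, size=n)
    es = _truncated_normal(
        rng, cfg.es_mean_diopters, cfg.es_sd_diopters, *cfg.es_bounds_diopters, size=n
    )

    means = np.where(is_male[:, None], cfg.count_means_male, cfg.count_means_female)
    sds = np.where(is_male[:, None], cfg.count_sds_male, cfg.count_sds_female)
    counts = np.maximum(0, np.rint(rng.normal(means, sds))).astype(int)  # (n, 4)

    eyes = pd.DataFrame(
        {
            "eye_id": [f"eye{i:04d}" for i in range(n)],
            "sex": sex,
            "age_yr": age,
            "bcva_logmar": bcva,
            "es_diopters": es,
            "axial_length_mm": al,
        }
    )
    for qi, s in enumerate(SECTORS):
        eyes[f"true_n_{s}"] = counts[:, qi]

    # flatten ampullae across the cohort
    eye_idx = np.repeat(np.arange(n)[:, None], 4, axis=1)
    quad_idx = np.broadcast_to(np.arange(4), (n, 4))
    eye_flat = np.repeat(eye_idx.ravel(), counts.ravel())
    quad_flat = np.repeat(quad_idx.ravel(), counts.ravel())
    m = len(eye_flat)

    # signed-disc-angle ranges per quadrant (UL, LL, UN, LN)
    az_lo = np.array([0.0, -90.0, 90.0, -180.0])[quad_flat]
    az_hi = np.array([90.0, 0.0, 180.0, -90.0])[quad_flat]
    azimuth = rng.uniform(az_lo, az_hi)

    radius = al[eye_flat] / 2.0
    slope = cfg.distance_al_slope_mm_per_mm
    d_mean = (
        np.asarray(cfg.distance_means_mm)[quad_flat]
        + slope * (al[eye_flat] - cfg.axial_length_mean_mm)
    )
    marginal_sd = np.asarray(cfg.distance_sds_mm)[quad_flat]
    resid_sd = np.sqrt(np.maximum(marginal_sd**2 - (slope * cfg.axial_length_sd_mm) ** 2, 0.04))
    dist = rng.normal(d_mean, resid_sd)
    bad = (dist <= cfg.min_distance_mm) | (dist >= np.pi * radius * 0.999)
    while np.any(bad):  # incompatible draws are resampled
        dist[bad] = rng.normal(d_mean[bad], resid_sd[bad])
        bad = (dist <= cfg.min_distance_mm) | (dist >= np.pi * radius * 0.999)

    # place on the sphere: start at the disc, initial bearing = disc->fovea
    # tangent rotated by the signed azimuth (positive superior), arc = d / R
    t_ref = fovea - np.dot(fovea, disc) * disc
    t_ref /= np.linalg.norm(t_ref)
    t_sup = np.cross(-disc, t_ref)  # superior tangent consistent with sign rule
    theta = dist / radius
    a_rad = np.radians(azimuth)
    bearing = np.outer(np.cos(a_rad), t_ref) + np.outer(np.sin(a_rad), t_sup)
    points = np.outer(np.cos(theta), disc) + np.sin(theta)[:, None] * bearing

    colat = np.degrees(np.arccos(np.clip(-points[:, 2], -1.0, 1.0)))
    rotations = {
        g: gaze_rotation_matrix(g, cfg.gaze_rotation_deg) for g in ("on_axis", "up", "down")
    }
    theta_by_view = {}
    for g, rot in rotations.items():
        pv = points @ rot  # rows are R^T p
        theta_by_view[g] = np.degrees(np.arccos(np.clip(-pv[:, 2], -1.0, 1.0)))
    view_names = list(rotations)
    theta_stack = np.stack([theta_by_view[g] for g in view_names], axis=1)
    best = np.argmin(theta_stack, axis=1) if m else np.array([], dtype=int)
    best_view = np.array(view_names, dtype=object)[best] if m else np.array([], dtype=object)

    ampullae = pd.DataFrame(
        {
            "eye_id": eyes["eye_id"].to_numpy()[eye_flat] if m else np.array([], dtype=object),
            "ampulla_id": np.concatenate(
                [np.arange(c) for c in counts.sum(axis=1) if c] or [np.array([], dtype=int)]
            ),
            "quadrant": np.array(SECTORS, dtype=object)[quad_flat] if m else np.array([], dtype=object),
            "x": points[:, 0] if m else np.array([]),
            "y": points[:, 1] if m else np.array([]),
            "z": points[:, 2] if m else np.array([]),
            "distance_mm": dist,
            "signed_angle_deg": azimuth,
            "colatitude_deg": colat,
            "best_view": best_view,
            "on_axis_visible": colat < cfg.visible_fov_deg / 2.0,
            "montage_visible": (theta_stack.min(axis=1) < cfg.visible_fov_deg / 2.0)
            if m
            else np.array([], dtype=bool),
        }
    )
    return PhantomTruth(
        config=cfg, disc=disc, fovea=fovea, eyes=eyes, ampullae=ampullae, rotations=rotations
    )


# ---------------------------------------------------------------------------
# Annotation emission


def _bifurcation_points(off_gaze: str, disc_nasal_deg: float) -> np.ndarray:
    """Five deterministic bifurcation sphere points, one per fundus region.

    Placed at the angular center of each 40-degree wedge at 45 degrees
    colatitude, on the hemisphere shared with the off-axis view (wedges are
    mirrored inferiorly for the down pair) — visible in both views for any
    plausible gaze rotation.
    """
    centers = np.array([10.0, 50.0, 90.0, 130.0, 170.0])
    if off_gaze == "down":
        centers = -centers
    phi = np.radians(centers)
    th = np.radians(45.0)
    return np.stack(
        [np.sin(th) * np.cos(phi), np.sin(th) * np.sin(phi), -np.cos(th) * np.ones_like(phi)],
        axis=-1,
    )


def eye_annotations(truth: PhantomTruth, eye_id: str, n_lines: int = 3) -> dict:
    """Noiseless annotation record for one phantom eye.

    The layout matches :mod:`fundusphere.io`: twelve alignment points (optic
    disc + five bifurcations for each of the up and down pairs), the on-axis
    fovea/disc pixels, and per-ampulla inflowing-vessel lines drawn in the
    view where the ampulla is most central.  Line bearings are deterministic
    functions of the ampulla's azimuth, fanned 180/n_lines degrees apart.
    """
    cfg = truth.config
    eye = truth.eye_model(eye_id)
    frame = truth.frame()
    rot = truth.rotations

    def to_px(points, gaze):
        pv = np.atleast_2d(points) @ rot[gaze]
        return forward_project(pv, frame, eye)

    correspondences = []
    for off in ("up", "down"):
        pts = []
        disc_on = to_px(truth.disc, "on_axis")[0]
        disc_off = to_px(truth.disc, off)[0]
        pts.append(
            {
                "role": "optic_disc",
                "region_id": None,
                "pixel_on": [float(disc_on[0]), float(disc_on[1])],
                "pixel_off": [float(disc_off[0]), float(disc_off[1])],
            }
        )
        bif = _bifurcation_points(off, cfg.disc_nasal_deg)
        bif_on = to_px(bif, "on_axis")
        bif_off = to_px(bif, off)
        for region, (pon, poff) in enumerate(zip(bif_on, bif_off), start=1):
            pts.append(
                {
                    "role": "vascular_bifurcation",
                    "region_id": region,
                    "pixel_on": [float(pon[0]), float(pon[1])],
                    "pixel_off": [float(poff[0]), float(poff[1])],
                }
            )
        correspondences.append({"off_gaze": off, "points": pts})

    amp = truth.ampullae[truth.ampullae["eye_id"] == eye_id]
    ampullae = []
    for _, row in amp.iterrows():
        p = np.array([row["x"], row["y"], row["z"]])
        view = row["best_view"]
        center = to_px(p, view)[0]
        base = np.radians(row["signed_angle_deg"])  # deterministic, eye-specific spread
        lines = []
        for j in range(n_lines):
            gamma = base + j * np.pi / n_lines
            direction = [float(np.cos(gamma)), float(-np.sin(gamma))]
            anchor = [
                float(center[0] + 30.0 * direction[0]),
                float(center[1] + 30.0 * direction[1]),
            ]
            lines.append({"anchor": anchor, "direction": direction})
        ampullae.append({"id": int(row["ampulla_id"]), "view": view, "lines": lines})

    fovea_px = to_px(truth.fovea, "on_axis")[0]
    disc_px = to_px(truth.disc, "on_axis")[0]
    return {
        "eye_id": eye_id,
        "laterality": cfg.laterality,
        "axial_length_mm": float(eye.axial_length_mm),
        "frame": {
            "width_px": frame.width_px,
            "height_px": frame.height_px,
            "fov_deg": frame.fov_deg,
            "center_px": [float(frame.center_px[0]), float(frame.center_px[1])],
        },
        "gaze_rotation_deg": cfg.gaze_rotation_deg,
        "fovea_px": {"view": "on_axis", "pixel": [float(fovea_px[0]), float(fovea_px[1])]},
        "disc_px": {"view": "on_axis", "pixel": [float(disc_px[0]), float(disc_px[1])]},
        "correspondences": correspondences,
        "ampullae": ampullae,
    }


def degrade(
    annotations: dict,
    landmark_noise_px: float,
    missing_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    line_lever_px: float = 50.0,
) -> dict:
    """Apply grader noise to an annotation record.

    Every pixel coordinate (alignment points, disc/fovea, line anchors) gets
    isotropic Gaussian jitter of SD ``landmark_noise_px``; line directions
    are jittered by perturbing a second point ``line_lever_px`` away along
    the line.  Ampullae are independently dropped with probability
    ``missing_rate``.  Zero noise and zero missing rate return an identical
    (deep-copied) record.
    """
    if landmark_noise_px < 0 or not (0.0 <= missing_rate < 1.0):
        raise ValueError("noise must be >= 0 and missing_rate in [0, 1)")
    rng = rng or np.random.default_rng()
    ann = copy.deepcopy(annotations)
    if landmark_noise_px == 0.0 and missing_rate == 0.0:
        return ann

    def jit(pt):
        return [float(pt[0] + rng.normal(0, landmark_noise_px)), float(pt[1] + rng.normal(0, landmark_noise_px))]

    for corr in ann["correspondences"]:
        for p in corr["points"]:
            p["pixel_on"] = jit(p["pixel_on"])
            p["pixel_off"] = jit(p["pixel_off"])
    for key in ("fovea_px", "disc_px"):
        ann[key]["pixel"] = jit(ann[key]["pixel"])

    kept = []
    for amp in ann["ampullae"]:
        if missing_rate > 0.0 and rng.random() < missing_rate:
            continue
        for ln in amp["lines"]:
            anchor = np.asarray(ln["anchor"], dtype=float)
            second = anchor + line_lever_px * np.asarray(ln["direction"], dtype=float)
            anchor = np.asarray(jit(anchor))
            second = np.asarray(jit(second))
            direction = second - anchor
            ln["anchor"] = [float(anchor[0]), float(anchor[1])]
            norm = float(np.linalg.norm(direction))
            ln["direction"] = [float(direction[0] / norm), float(direction[1] / norm)]
        kept.append(amp)
    ann["ampullae"] = kept
    return ann


# ---------------------------------------------------------------------------
# Optional raster rendering


def render_views(
    truth: PhantomTruth,
    eye_id: str,
    size: int = 256,
    background: float = 0.85,
    vessel: float = 0.25,
    line_length_px: int = 24,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Render simple per-view rasters: dark inflowing vessels on a bright fundus.

    Not photorealistic — just enough structure (converging line segments per
    ampulla, smooth background, optional noise) to exercise the enhancement,
    binarization and montage-composition stages end to end.
    """
    from skimage.draw import line as draw_line

    cfg = truth.config
    eye = truth.eye_model(eye_id)
    frame = FundusFrame(size, size, fov_deg=cfg.fov_deg)
    rng = rng or np.random.default_rng(cfg.seed)
    amp = truth.ampullae[truth.ampullae["eye_id"] == eye_id]
    points = amp[["x", "y", "z"]].to_numpy()
    images: dict[str, np.ndarray] = {}
    yy, xx = np.mgrid[0:size, 0:size]
    shading = 0.05 * np.cos(2 * np.pi * xx / size) * np.cos(2 * np.pi * yy / size)
    for gaze, rot in truth.rotations.items():
        img = np.full((size, size), background) + shading
        if len(points):
            pv = points @ rot
            theta = np.degrees(np.arccos(np.clip(-pv[:, 2], -1.0, 1.0)))
            visible = theta < cfg.fov_deg / 2.0 - 1.0
            if visible.any():
                px = forward_project(pv[visible], frame, eye)
                for (cx, cy), az in zip(px, amp["signed_angle_deg"].to_numpy()[visible]):
                    for j in range(3):
                        gamma = np.radians(az) + j * np.pi / 3
                        ex = int(round(cx + line_length_px * np.cos(gamma)))
                        ey = int(round(cy - line_length_px * np.sin(gamma)))
                        rr, cc = draw_line(int(round(cy)), int(round(cx)), ey, ex)
                        ok = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
                        img[rr[ok], cc[ok]] = vessel
        if noise_sd > 0.0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        images[gaze] = np.clip(img, 0.0, 1.0)
    return images
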