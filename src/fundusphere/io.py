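"""Annotation/config file formats and schema validation.

Annotations are JSON, one file per eye, with 0-based pixels; eye/run
configuration is YAML.  :func:`validate_annotations` enforces the montage
contract — two correspondence pairs of six points each (the optic disc plus
one vascular bifurcation per fundus region, twelve alignment points in all)
and at least two inflowing-vessel lines per ampulla — and returns an
itemized violation list rather than failing on the first problem.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from .geometry import EyeModel, FundusFrame

__all__ = [
    "RunConfig",
    "load_annotations",
    "save_annotations",
    "validate_annotations",
    "load_eye_config",
    "save_eye_config",
    "frame_and_eye_from_annotations",
]


class RunConfig(BaseModel):
    """Pipeline run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    out_dir: str = "fundusphere_run"
    seed: int = 0
    n_eyes: int = 74
    landmark_noise_px: float = 0.0
    missing_rate: float = 0.0
    render_rasters: bool = False
    run_stats: bool = True
    verbosity: int = 1


def load_annotations(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)


def save_annotations(annotations: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(annotations, fh, indent=1, sort_keys=True)
        fh.write("\n")


def validate_annotations(annotations) -> list[str]:
    """Schema check; returns a list of human-readable violations (empty = valid)."""
    ann = load_annotations(annotations) if isinstance(annotations, (str, Path)) else annotations
    problems: list[str] = []
    for key in ("eye_id", "axial_length_mm", "frame", "fovea_px", "disc_px"):
        if key not in ann:
            problems.append(f"missing required key {key!r}")

    corrs = ann.get("correspondences", [])
    if len(corrs) != 2:
        problems.append(f"expected 2 correspondence pairs (up and down), found {len(corrs)}")
    for corr in corrs:
        gaze = corr.get("off_gaze", "?")
        points = corr.get("points", [])
        discs = [p for p in points if p.get("role") == "optic_disc"]
        bifs = [p for p in points if p.get("role") == "vascular_bifurcation"]
        if len(points) != 6 or len(discs) != 1:
            problems.append(
                f"pair {gaze}: expected 6 points (1 optic disc + 5 bifurcations), found "
                f"{len(points)} with {len(discs)} disc point(s)"
            )
        if len(bifs) != 5 or sorted(p.get("region_id") for p in bifs) != [1, 2, 3, 4, 5]:
            problems.append(f"pair {gaze}: expected 5 bifurcations, one per region 1-5")
        for p in points:
            for side in ("pixel_on", "pixel_off"):
                if len(p.get(side, [])) != 2:
                    problems.append(f"pair {gaze}: point missing {side}")

    for amp in ann.get("ampullae", []):
        if len(amp.get("lines", [])) < 2:
            problems.append(f"ampulla {amp.get('id', '?')}: fewer than 2 inflowing-vessel lines")
        if amp.get("view") not in ("on_axis", "up", "down"):
            problems.append(f"ampulla {amp.get('id', '?')}: unknown view {amp.get('view')!r}")
    return problems


def frame_and_eye_from_annotations(ann: dict) -> tuple[FundusFrame, EyeModel]:
    fr = ann["frame"]
    frame = FundusFrame(
        width_px=int(fr["width_px"]),
        height_px=int(fr["height_px"]),
        center_px=tuple(fr["center_px"]) if "center_px" in fr else None,
        fov_deg=float(fr.get("fov_deg", 200.0)),
    )
    eye = EyeModel(float(ann["axial_length_mm"]), ann.get("laterality", "OD"))
    return frame, eye


def load_eye_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def save_eye_config(config: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
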