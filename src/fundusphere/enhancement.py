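"""Choroidal-vessel enhancement and binarization (documented stand-in).

The enhancement used on the study montages comes from the authors' earlier
work and is only cited, never specified.  This module provides a
deterministic, testable pipeline with the same role — make the large
choroidal veins separable from the background — and records full provenance
so the original method can be slotted in:

1. select the long-wavelength (choroid-dominant) channel;
2. remove the large-scale background with a wide median filter;
3. local contrast equalization (CLAHE);
4. normalization to [0, 1].

Every step and its parameters are appended to the ``provenance`` list of the
returned :class:`EnhancedImage`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import exposure, filters

__all__ = ["DegenerateInputError", "EnhancedImage", "enhance_choroid", "binarize_vessels"]


class DegenerateInputError(ValueError):
    """Empty or constant image: nothing to enhance."""


@dataclass
class EnhancedImage:
    data: np.ndarray  # float, normalized to [0, 1]
    provenance: list[dict] = field(default_factory=list)


def _rescale01(arr: np.ndarray) -> np.ndarray:
    lo, hi = float(np.nanmin(arr)), float(np.nanmax(arr))
    if not np.isfinite(lo) or hi - lo <= 0.0:
        raise DegenerateInputError("constant or empty image")
    return (arr - lo) / (hi - lo)


def enhance_choroid(
    composite,
    channel: int = 0,
    background_fraction: float = 0.125,
    clahe_clip: float = 0.01,
) -> EnhancedImage:
    """Enhance choroidal vasculature in a composite or raw fundus raster.

    Parameters
    ----------
    composite:
        2D array, or 3D ``(H, W, C)`` from which ``channel`` is taken (the
        long-wavelength channel carries most choroidal signal).
    background_fraction:
        Median-filter kernel width as a fraction of the image width; removes
        illumination and large-scale fundus shading.
    clahe_clip:
        CLAHE clip limit.

    Raises
    ------
    DegenerateInputError
        For empty or constant input.
    """
    arr = np.asarray(composite, dtype=float)
    prov: list[dict] = []
    if arr.ndim == 3:
        arr = arr[..., channel]
        prov.append({"step": "select_channel", "channel": channel})
    if arr.size == 0 or not np.isfinite(arr).any():
        raise DegenerateInputError("empty image")
    if np.nanmax(arr) - np.nanmin(arr) <= 0.0:
        raise DegenerateInputError("constant image")

    k = max(3, int(round(arr.shape[1] * background_fraction)) | 1)
    background = ndimage.median_filter(arr, size=k)
    flat = arr - background
    prov.append({"step": "median_background_subtraction", "kernel_px": k})

    flat = _rescale01(flat)
    prov.append({"step": "rescale", "range": [0.0, 1.0]})

    eq = exposure.equalize_adapthist(flat, clip_limit=clahe_clip)
    prov.append({"step": "clahe", "clip_limit": clahe_clip})

    out = _rescale01(eq)
    prov.append({"step": "rescale", "range": [0.0, 1.0]})
    return EnhancedImage(data=out, provenance=prov)


def binarize_vessels(
    enhanced,
    method: str = "otsu",
    threshold: float | None = None,
    vessels_dark: bool = True,
) -> np.ndarray:
    """Binary vessel mask from an enhanced image.

    ``method="otsu"`` maximizes inter-class variance; ``method="fixed"`` uses
    the given ``threshold``.  Vessels are taken as the dark class by default
    (choroidal veins absorb the long-wavelength illumination).  A constant
    image yields an empty mask.
    """
    data = enhanced.data if isinstance(enhanced, EnhancedImage) else np.asarray(enhanced, dtype=float)
    if data.size == 0 or np.nanmax(data) - np.nanmin(data) <= 0.0:
        return np.zeros_like(data, dtype=bool)
    if method == "otsu":
        thr = filters.threshold_otsu(data)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return data < thr if vessels_dark else data > thr
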