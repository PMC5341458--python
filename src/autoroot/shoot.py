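"""Top-down shoot traits: leaf area and mean leaf hue.

A second camera photographs the plate from above against a white background.
Leaf pixels are separated from the background by saturation alone — white
has saturation 0, plant material is strongly coloured — so "leaf" means any
pixel whose HSV saturation exceeds a low threshold (default 20% of full
scale, strict inequality).  The two traits are the count of leaf pixels and
their circular mean hue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.colors import rgb_to_hsv

from .errors import ImageFormatError

__all__ = ["LeafMask", "leaf_mask", "leaf_area", "leaf_hue"]

DEFAULT_SAT_THRESHOLD = 0.20


@dataclass(frozen=True)
class LeafMask:
    """Boolean leaf-pixel mask over a top-down well region."""

    mask: np.ndarray
    sat_threshold: float = DEFAULT_SAT_THRESHOLD


def _to_hsv(region: np.ndarray) -> np.ndarray:
    region = np.asarray(region)
    if region.ndim != 3 or region.shape[2] != 3:
        raise ImageFormatError(f"expected H×W×3 colour region, got shape {region.shape}")
    return rgb_to_hsv(region.astype(np.float64) / 255.0)


def leaf_mask(
    top_well: np.ndarray, sat_threshold: float = DEFAULT_SAT_THRESHOLD
) -> LeafMask:
    """Mask of non-white pixels: HSV saturation strictly above the threshold."""
    hsv = _to_hsv(top_well)
    return LeafMask(mask=hsv[:, :, 1] > sat_threshold, sat_threshold=sat_threshold)


def leaf_area(mask: LeafMask) -> int:
    """Number of leaf pixels in the region."""
    return int(mask.mask.sum())


def leaf_hue(top_well: np.ndarray, mask: LeafMask) -> float | None:
    """Circular mean hue of the leaf pixels, in degrees [0°, 360°).

    Hue is an angle, so the mean is taken over unit vectors; an arithmetic
    mean would average red hues near 10° and 350° to cyan instead of red.
    Returns None when the mask is empty.
    """
    if not mask.mask.any():
        return None
    hsv = _to_hsv(top_well)
    hues = hsv[:, :, 0][mask.mask] * 2.0 * np.pi  # matplotlib hue is in [0, 1)
    angle = np.arctan2(np.sin(hues).mean(), np.cos(hues).mean())
    return float(np.degrees(angle) % 360.0)
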