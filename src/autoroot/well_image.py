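"""Plate-image loading, grayscale conversion, contrast stretching and well extraction.

A plate photograph contains a horizontal row of agar-filled growth wells.
Because the plates are positioned robotically, the pixel rectangle of every
well is fixed across a batch and is supplied explicitly in the run
configuration rather than detected from the image.

Coordinate convention (used by every module): 0-based, origin at the top-left
corner, ``x`` is the column index increasing rightward, ``y`` the row index
increasing downward.  Rectangles are half-open: ``(x0, y0, w, h)`` covers
columns ``x0 .. x0+w-1`` and rows ``y0 .. y0+h-1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import imageio.v3 as iio

from .errors import ConfigError, ImageFormatError

__all__ = [
    "WellGrid",
    "GrayWell",
    "StretchBounds",
    "load_plate_image",
    "to_grayscale",
    "contrast_stretch",
    "extract_wells",
]

#: ITU-R BT.601 luma weights for RGB -> gray conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class WellGrid:
    """Geometry of the wells inside one plate image.

    Parameters
    ----------
    well_rects
        One ``(x0, y0, width, height)`` rectangle per well, left to right.
    strip_fraction
        Fraction of the well height forming the top strip searched for
        seed points (seeds are always sown above this line), default 0.05.
    """

    well_rects: tuple[tuple[int, int, int, int], ...]
    strip_fraction: float = 0.05

    def __init__(self, well_rects: Sequence[Sequence[int]], strip_fraction: float = 0.05):
        rects = tuple(tuple(int(v) for v in r) for r in well_rects)
        for i, r in enumerate(rects):
            if len(r) != 4:
                raise ConfigError(f"well {i}: rectangle must be (x0, y0, w, h), got {r!r}")
            if r[2] <= 0 or r[3] <= 0:
                raise ConfigError(f"well {i}: non-positive size in rectangle {r}")
            if r[0] < 0 or r[1] < 0:
                raise ConfigError(f"well {i}: negative origin in rectangle {r}")
        if not 0.0 < strip_fraction < 1.0:
            raise ConfigError(f"strip_fraction must be in (0, 1), got {strip_fraction}")
        object.__setattr__(self, "well_rects", rects)
        object.__setattr__(self, "strip_fraction", float(strip_fraction))

    @property
    def n_wells(self) -> int:
        return len(self.well_rects)

    @classmethod
    def uniform(
        cls,
        n_wells: int,
        well_width: int,
        well_height: int,
        x0: int = 0,
        y0: int = 0,
        gap: int = 0,
        strip_fraction: float = 0.05,
    ) -> "WellGrid":
        """Regular left-to-right grid of identical wells separated by ``gap`` px."""
        rects = [
            (x0 + i * (well_width + gap), y0, well_width, well_height)
            for i in range(n_wells)
        ]
        return cls(rects, strip_fraction=strip_fraction)

    def validate_for(self, image_shape: tuple[int, int]) -> None:
        """Raise :class:`ConfigError` if any rectangle leaves the image bounds."""
        h, w = image_shape[:2]
        for i, (rx, ry, rw, rh) in enumerate(self.well_rects):
            if rx + rw > w or ry + rh > h:
                raise ConfigError(
                    f"well {i}: rectangle {(rx, ry, rw, rh)} exceeds image bounds {(w, h)}"
                )


@dataclass(frozen=True)
class GrayWell:
    """One well's grayscale intensity field, normalised into [0, 1].

    ``intensities[y, x]`` is the normalised intensity I(x, y); the array shape
    is ``(height, width)``.
    """

    intensities: np.ndarray
    well_index: int = 0

    def __post_init__(self):
        arr = np.asarray(self.intensities, dtype=np.float64)
        if arr.ndim != 2 or arr.size == 0:
            raise ConfigError("GrayWell requires a non-empty 2-D intensity array")
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise ConfigError("GrayWell intensities must lie in [0, 1]")
        object.__setattr__(self, "intensities", arr)

    @property
    def height(self) -> int:
        return self.intensities.shape[0]

    @property
    def width(self) -> int:
        return self.intensities.shape[1]


@dataclass(frozen=True)
class StretchBounds:
    """Fixed 8-bit input range mapped onto the full 0–255 output range.

    One pair serves a whole batch: plate lighting is fixed, so the intensity
    ranges of background and root material are stable across images and are
    determined once, up front.
    """

    low: int
    high: int

    def __post_init__(self):
        if not (0 <= self.low < self.high <= 255):
            raise ConfigError(
                f"stretch bounds require 0 <= low < high <= 255, got ({self.low}, {self.high})"
            )


def load_plate_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG plate image as an 8-bit H×W×3 array.

    Grayscale inputs are replicated to three identical channels; an alpha
    channel, if present, is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    try:
        img = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - normalise reader errors
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if img.dtype != np.uint8:
        raise ImageFormatError(
            f"{path}: only 8-bit images are supported, got dtype {img.dtype}"
        )
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    elif img.ndim == 3 and img.shape[2] == 4:
        img = img[:, :, :3]
    elif img.ndim == 3 and img.shape[2] == 3:
        pass
    else:
        raise ImageFormatError(f"{path}: unsupported image layout {img.shape}")
    return np.ascontiguousarray(img)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to 8-bit gray via BT.601 luma weights."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ImageFormatError(f"expected H×W×3 input, got shape {image.shape}")
    r, g, b = LUMA_WEIGHTS
    gray = r * image[:, :, 0] + g * image[:, :, 1] + b * image[:, :, 2]
    return np.rint(gray).astype(np.uint8)


def contrast_stretch(image: np.ndarray, bounds: StretchBounds) -> np.ndarray:
    """Linearly map the 8-bit range [low, high] onto [0, 255].

    Values at or below ``low`` map to 0, values at or above ``high`` to 255,
    and intermediate values are scaled linearly and rounded.  The mapping is
    monotone non-decreasing and is the identity for bounds (0, 255).
    """
    image = np.asarray(image)
    v = image.astype(np.float64)
    scaled = 255.0 * (v - bounds.low) / (bounds.high - bounds.low)
    return np.rint(np.clip(scaled, 0.0, 255.0)).astype(np.uint8)


def extract_wells(image: np.ndarray, grid: WellGrid) -> list[GrayWell]:
    """Cut a 2-D 8-bit plate image into per-well [0, 1] intensity fields."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ImageFormatError(f"expected a 2-D grayscale image, got shape {image.shape}")
    grid.validate_for(image.shape)
    wells = []
    for i, (rx, ry, rw, rh) in enumerate(grid.well_rects):
        sub = image[ry : ry + rh, rx : rx + rw].astype(np.float64) / 255.0
        wells.append(GrayWell(sub, well_index=i))
    return wells
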