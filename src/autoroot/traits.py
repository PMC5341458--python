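"""Likelihood-weighted proxy traits of the root system.

Every trait is a weighted image statistic: each pixel contributes in
proportion to its root likelihood L(x, y), so no pixel is ever classified
as root or background outright.  Values are in pixel units ("arbitrary
units"); the traits are proxies meant to correlate with classical manual
measures (proxy-depth with root length, Q3 mass with deep root material,
orientation brackets with lateral-root spread), not to equal them.

Trait catalogue (one record per well):

* centroid          — likelihood-weighted centre of mass (x, y)
* mass, mass_norm   — total likelihood, raw and per-pixel
* width/depth (M)   — bounding extremities scored by the product L·coordinate
* width/depth (p95) — box enclosing 95% of total likelihood
* depth (p99)       — depth enclosing 99% of total likelihood
* quadrant mass     — mass split over four stacked horizontal bands Q0..Q3
* orientation       — ten angle brackets from 0° (horizontal) to 90°
                      (vertical) accumulating likelihood mass
* quadrant orientation — four brackets per quadrant, 16 values
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import EmptyWellError
from .likelihood import LikelihoodMap
from .well_image import GrayWell

__all__ = [
    "OrientationField",
    "TraitRecord",
    "centroid",
    "mass",
    "bbox_argmax",
    "bbox_quantile",
    "quadrant_mass",
    "quadrant_bands",
    "orientation_field",
    "orientation_histogram",
    "quadrant_orientation",
    "compute_traits",
]

N_ORIENT_BINS = 10
N_QUADRANTS = 4
N_QUAD_BRACKETS = 4

# Relative slack when locating quantile boxes, so exact-fraction boundaries
# (e.g. 95 of 100 uniform rows) are not missed to floating-point rounding.
_QUANTILE_RTOL = 1e-9


@dataclass(frozen=True)
class OrientationField:
    """Per-pixel structure angle and gradient magnitude.

    ``theta`` is the local structure direction in degrees, 0° for horizontal
    material and 90° for vertical material.  It is the complement of the
    Sobel gradient direction: the intensity gradient across a bright line is
    perpendicular to the line's axis, so a vertical root (strong horizontal
    gradient at its flanks) maps to theta = 90°.  ``magnitude`` is the Sobel
    gradient magnitude; pixels with zero magnitude have no defined
    orientation and are excluded from orientation statistics.
    """

    theta: np.ndarray
    magnitude: np.ndarray


def centroid(lmap: LikelihoodMap) -> tuple[float, float]:
    """Likelihood-weighted centre of mass, as (x, y) pixel coordinates."""
    L = lmap.L
    total = L.sum()
    if total <= 0:
        raise EmptyWellError("centroid undefined for a zero likelihood map")
    H, W = L.shape
    xs = np.arange(W, dtype=np.float64)
    ys = np.arange(H, dtype=np.float64)
    cx = float((L.sum(axis=0) * xs).sum() / total)
    cy = float((L.sum(axis=1) * ys).sum() / total)
    return cx, cy


def mass(lmap: LikelihoodMap) -> tuple[float, float]:
    """Total likelihood over the well: raw sum and per-pixel mean.

    The raw sum plays the role of a thresholded pixel count in classical
    pipelines; the per-pixel form removes the dependence on well size.
    """
    raw = float(lmap.L.sum())
    return raw, raw / lmap.L.size


def bbox_argmax(lmap: LikelihoodMap) -> tuple[int, int]:
    """Bounding extremities scored by the product of likelihood and position.

    The right edge is the column of the pixel maximising ``L(x,y)·x``; the
    left edge uses the mirrored coordinate ``W-1-x``, and the top/bottom
    edges the analogous row products.  A dim far pixel can outscore a bright
    near one — the extremity is a likelihood-weighted compromise, not a hard
    boundary.  Returns ``(width_m, depth_m)`` where ``depth_m`` is the
    bottom-extremity row, i.e. the distance grown from the top of the well
    (the proxy for root-system length).
    """
    L = lmap.L
    if L.sum() <= 0:
        raise EmptyWellError("bounding box undefined for a zero likelihood map")
    H, W = L.shape
    xs = np.arange(W, dtype=np.float64)
    ys = np.arange(H, dtype=np.float64)[:, None]
    right = int(np.argmax(L * xs) % W)
    left = int(np.argmax(L * (W - 1 - xs)) % W)
    bottom = int(np.argmax(L * ys) // W)
    width_m = right - left + 1
    depth_m = bottom
    return width_m, depth_m


def bbox_quantile(lmap: LikelihoodMap, fraction: float = 0.95) -> tuple[int, int]:
    """Box enclosing the given fraction of total likelihood.

    Depth is one-sided from the top of the well (roots grow downward from
    seeds at the top): the smallest row index at which the cumulative
    row-marginal reaches ``fraction`` of the total.  Width trims
    ``(1 - fraction)/2`` of the mass from each side of the column-marginal
    and returns the length of the remaining central interval.
    """
    L = lmap.L
    total = L.sum()
    if total <= 0:
        raise EmptyWellError("quantile box undefined for a zero likelihood map")
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    eps = _QUANTILE_RTOL * total
    row_marginal = L.sum(axis=1)
    cum_rows = np.cumsum(row_marginal)
    depth = int(np.searchsorted(cum_rows, fraction * total - eps))
    col_marginal = L.sum(axis=0)
    cum_cols = np.cumsum(col_marginal)
    tail = (1.0 - fraction) / 2.0 * total
    left = int(np.searchsorted(cum_cols, tail + eps))
    # mirrored cumulative from the right
    cum_right = np.cumsum(col_marginal[::-1])
    right = L.shape[1] - 1 - int(np.searchsorted(cum_right, tail + eps))
    width = max(right - left + 1, 0)
    return width, depth


def quadrant_bands(height: int) -> list[tuple[int, int]]:
    """Row ranges of the four stacked bands Q0 (top) .. Q3 (bottom).

    Bands are ``height // 4`` rows tall; remainder rows join the bottom band.
    """
    h = height // N_QUADRANTS
    edges = [0, h, 2 * h, 3 * h, height]
    return [(edges[i], edges[i + 1]) for i in range(N_QUADRANTS)]


def quadrant_mass(lmap: LikelihoodMap) -> np.ndarray:
    """Total likelihood within each of the four horizontal bands, Q0..Q3."""
    L = lmap.L
    return np.array([L[y0:y1].sum() for y0, y1 in quadrant_bands(L.shape[0])])


def orientation_field(well: GrayWell) -> OrientationField:
    """Local structure angle from Sobel gradients.

    Gradients Gx, Gy come from the standard 3×3 Sobel kernels with replicate
    padding at the borders.  The gradient direction
    ``phi = atan2(|Gy|, |Gx|)`` lies in [0°, 90°]; the structure angle is its
    complement ``theta = 90° - phi`` so that a vertical bright line scores
    90° and a horizontal one 0°.
    """
    arr = well.intensities
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError("orientation field requires a well of at least 3x3 pixels")
    gx = ndimage.sobel(arr, axis=1, mode="nearest")
    gy = ndimage.sobel(arr, axis=0, mode="nearest")
    magnitude = np.hypot(gx, gy)
    phi = np.degrees(np.arctan2(np.abs(gy), np.abs(gx)))
    theta = 90.0 - phi
    return OrientationField(theta=theta, magnitude=magnitude)


def orientation_histogram(
    lmap: LikelihoodMap, field_: OrientationField, n_bins: int = N_ORIENT_BINS
) -> np.ndarray:
    """Likelihood mass per orientation bracket over [0°, 90°].

    Brackets are equal half-open intervals (the last one closed at 90°).
    Each pixel with non-zero gradient magnitude adds its likelihood to the
    bracket containing its structure angle; flat pixels contribute nothing.
    """
    L = lmap.L
    if L.shape != field_.theta.shape:
        raise ValueError("likelihood map and orientation field shapes differ")
    valid = field_.magnitude > 0
    idx = np.minimum(
        (field_.theta[valid] / (90.0 / n_bins)).astype(np.int64), n_bins - 1
    )
    return np.bincount(idx, weights=L[valid], minlength=n_bins)


def quadrant_orientation(
    lmap: LikelihoodMap, field_: OrientationField
) -> np.ndarray:
    """Likelihood mass per (quadrant, orientation bracket): 4×4 = 16 values.

    The four horizontal bands of :func:`quadrant_mass` are crossed with four
    equal angle brackets over [0°, 90°]; returned flattened in band-major
    order (Q0 brackets first).
    """
    L = lmap.L
    if L.shape != field_.theta.shape:
        raise ValueError("likelihood map and orientation field shapes differ")
    out = np.zeros((N_QUADRANTS, N_QUAD_BRACKETS))
    for q, (y0, y1) in enumerate(quadrant_bands(L.shape[0])):
        valid = field_.magnitude[y0:y1] > 0
        idx = np.minimum(
            (field_.theta[y0:y1][valid] / (90.0 / N_QUAD_BRACKETS)).astype(np.int64),
            N_QUAD_BRACKETS - 1,
        )
        out[q] = np.bincount(idx, weights=L[y0:y1][valid], minlength=N_QUAD_BRACKETS)
    return out.ravel()


@dataclass
class TraitRecord:
    """All proxy trait values for one well, CSV-serialisable.

    ``empty_flag`` marks wells with no detected seed points; all numeric
    traits are zero for such wells and ``leaf_hue`` is absent.
    """

    image_id: str
    well_index: int
    empty_flag: bool = False
    centroid_x: float = 0.0
    centroid_y: float = 0.0
    mass: float = 0.0
    mass_norm: float = 0.0
    width_m: int = 0
    depth_m: int = 0
    width_p95: int = 0
    depth_p95: int = 0
    depth_p99: int = 0
    quadrant_mass: np.ndarray = field(default_factory=lambda: np.zeros(N_QUADRANTS))
    orientation: np.ndarray = field(default_factory=lambda: np.zeros(N_ORIENT_BINS))
    quadrant_orientation: np.ndarray = field(
        default_factory=lambda: np.zeros(N_QUADRANTS * N_QUAD_BRACKETS)
    )
    leaf_area: Optional[int] = None
    leaf_hue: Optional[float] = None

    @staticmethod
    def columns() -> list[str]:
        """Stable CSV column order."""
        cols = ["image_id", "well_index", "empty_flag"]
        cols += ["centroid_x", "centroid_y", "mass", "mass_norm"]
        cols += ["width_m", "depth_m", "width_p95", "depth_p95", "depth_p99"]
        cols += [f"q{i}_mass" for i in range(N_QUADRANTS)]
        cols += [f"orient_{i}" for i in range(N_ORIENT_BINS)]
        cols += [
            f"q{q}_orient_{b}"
            for q in range(N_QUADRANTS)
            for b in range(N_QUAD_BRACKETS)
        ]
        cols += ["leaf_area", "leaf_hue"]
        return cols

    def to_dict(self) -> dict:
        d = {
            "image_id": self.image_id,
            "well_index": self.well_index,
            "empty_flag": int(self.empty_flag),
            "centroid_x": self.centroid_x,
            "centroid_y": self.centroid_y,
            "mass": self.mass,
            "mass_norm": self.mass_norm,
            "width_m": self.width_m,
            "depth_m": self.depth_m,
            "width_p95": self.width_p95,
            "depth_p95": self.depth_p95,
            "depth_p99": self.depth_p99,
        }
        for i in range(N_QUADRANTS):
            d[f"q{i}_mass"] = float(self.quadrant_mass[i])
        for i in range(N_ORIENT_BINS):
            d[f"orient_{i}"] = float(self.orientation[i])
        for q in range(N_QUADRANTS):
            for b in range(N_QUAD_BRACKETS):
                d[f"q{q}_orient_{b}"] = float(
                    self.quadrant_orientation[q * N_QUAD_BRACKETS + b]
                )
        d["leaf_area"] = self.leaf_area if self.leaf_area is not None else ""
        d["leaf_hue"] = self.leaf_hue if self.leaf_hue is not None else ""
        return d

    @classmethod
    def empty(cls, image_id: str, well_index: int) -> "TraitRecord":
        """All-zero record for a well with no detected seed points."""
        return cls(image_id=image_id, well_index=well_index, empty_flag=True)


def compute_traits(
    lmap: LikelihoodMap,
    well: GrayWell,
    image_id: str = "",
    well_index: int | None = None,
) -> TraitRecord:
    """Compute the full root-trait record for one well."""
    idx = well.well_index if well_index is None else well_index
    if lmap.L.sum() <= 0:
        return TraitRecord.empty(image_id, idx)
    cx, cy = centroid(lmap)
    raw_mass, mass_norm = mass(lmap)
    width_m, depth_m = bbox_argmax(lmap)
    width_p95, depth_p95 = bbox_quantile(lmap, 0.95)
    _, depth_p99 = bbox_quantile(lmap, 0.99)
    field_ = orientation_field(well)
    return TraitRecord(
        image_id=image_id,
        well_index=idx,
        empty_flag=False,
        centroid_x=cx,
        centroid_y=cy,
        mass=raw_mass,
        mass_norm=mass_norm,
        width_m=width_m,
        depth_m=depth_m,
        width_p95=width_p95,
        depth_p95=depth_p95,
        depth_p99=depth_p99,
        quadrant_mass=quadrant_mass(lmap),
        orientation=orientation_histogram(lmap, field_),
        quadrant_orientation=quadrant_orientation(lmap, field_),
    )
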