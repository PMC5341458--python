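"""Seed-point detection and the probabilistic root-likelihood map.

Instead of a binary intensity threshold, every pixel receives a likelihood of
belonging to the root system.  Candidate root origins ("seed points") are
local intensity maxima found row-by-row in a thin strip at the top of the
well (seeds are always sown above this line).  A multi-source shortest-path
search then assigns every pixel the cheapest travel cost from any seed, where
travel over bright (root-like) pixel pairs is cheap and travel over dark
background is expensive.  The likelihood is the complement of the normalised
distance:

    L(x, y) = (1 - dijkstra(x, y) / norm_max) ** n

clamped into [0, 1].  Bright noise specks disconnected from the root score
low automatically because every path to them crosses dark background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _dijkstra
from ._dijkstra import dijkstra_grid
from .errors import ConfigError, EmptyWellError
from .well_image import GrayWell

__all__ = [
    "SeedPoints",
    "DistanceMap",
    "LikelihoodMap",
    "detect_seed_points",
    "edge_weight",
    "multi_source_dijkstra",
    "likelihood",
    "theoretical_norm_max",
    "WEIGHT_MODES",
]

SQRT2 = math.sqrt(2.0)

#: Accepted treatments of the diagonal negative-weight case of the raw
#: weight formula (see :func:`edge_weight`).
WEIGHT_MODES = ("clamped", "scaled")

#: Default minimum normalised intensity for a local maximum to count as a
#: seed; suppresses seeding on background noise in empty wells.  Set to 0
#: for the literal plain-local-maxima behaviour.
DEFAULT_MIN_SEED_INTENSITY = 0.2


@dataclass(frozen=True)
class SeedPoints:
    """Candidate root-origin pixels, as (x, y) coordinates in the top strip."""

    points: tuple[tuple[int, int], ...]

    def __init__(self, points: Sequence[Sequence[int]]):
        object.__setattr__(
            self, "points", tuple((int(x), int(y)) for x, y in points)
        )

    def __len__(self) -> int:
        return len(self.points)

    def __bool__(self) -> bool:
        return bool(self.points)


@dataclass(frozen=True)
class DistanceMap:
    """Per-pixel shortest-path cost from the nearest seed point."""

    distances: np.ndarray
    source: SeedPoints

    @property
    def max(self) -> float:
        return float(self.distances.max())


@dataclass(frozen=True)
class LikelihoodMap:
    """Per-pixel root likelihood L(x, y) in [0, 1]."""

    L: np.ndarray
    norm_max: float
    exponent: float = 1.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.L.shape

    @property
    def total(self) -> float:
        return float(self.L.sum())


def detect_seed_points(
    well: GrayWell,
    strip_fraction: float = 0.05,
    min_intensity: float = DEFAULT_MIN_SEED_INTENSITY,
) -> SeedPoints:
    """Find per-row local intensity maxima in the top strip of a well.

    The strip spans the top ``ceil(strip_fraction * height)`` pixel rows.
    Within each row, a pixel strictly brighter than both horizontal
    neighbours is a seed; a plateau of equal maximal values contributes its
    centre pixel; border pixels compare only against their single existing
    neighbour.  Maxima dimmer than ``min_intensity`` are discarded.

    Returns an empty :class:`SeedPoints` when nothing qualifies; callers
    treat such wells as empty rather than aborting a batch.
    """
    if not 0.0 < strip_fraction < 1.0:
        raise ConfigError(f"strip_fraction must be in (0, 1), got {strip_fraction}")
    strip_rows = math.ceil(strip_fraction * well.height)
    arr = well.intensities
    width = well.width
    points: list[tuple[int, int]] = []
    for y in range(strip_rows):
        row = arr[y]
        x = 0
        while x < width:
            # run of equal values [x, end)
            end = x + 1
            while end < width and row[end] == row[x]:
                end += 1
            left_ok = x == 0 or row[x - 1] < row[x]
            right_ok = end == width or row[end] < row[x]
            if left_ok and right_ok and row[x] >= min_intensity:
                points.append(((x + end - 1) // 2, y))
            x = end
    return SeedPoints(points)


def edge_weight(
    ip: float, iq: float, diagonal: bool = False, mode: str = "clamped"
) -> float:
    """Weight of the pixel-graph edge between intensities ``ip`` and ``iq``.

    The raw weight is ``1 - alpha * ip * iq`` with ``alpha = 1`` for
    orthogonal neighbours and ``sqrt(2)`` for diagonal ones (longer
    centre-to-centre distance).  For diagonal steps between very bright
    pixels the raw value goes negative; mode ``"clamped"`` (default) clamps
    it to 0 so Dijkstra's non-negativity precondition holds, while mode
    ``"scaled"`` uses ``alpha * (1 - ip*iq)`` which is non-negative by
    construction and identical for orthogonal steps.
    """
    if not (0.0 <= ip <= 1.0 and 0.0 <= iq <= 1.0):
        raise ValueError(f"intensities must lie in [0, 1], got ({ip}, {iq})")
    alpha = SQRT2 if diagonal else 1.0
    if mode == "clamped":
        return max(0.0, 1.0 - alpha * (ip * iq))
    if mode == "scaled":
        return alpha * (1.0 - ip * iq)
    raise ConfigError(f"unknown weight mode {mode!r}; expected one of {WEIGHT_MODES}")


def multi_source_dijkstra(
    well: GrayWell, seeds: SeedPoints, weight_mode: str = "clamped"
) -> DistanceMap:
    """Cheapest 8-connected path cost from any seed to every pixel.

    All weights are finite, so every pixel of the well is reachable and all
    distances are finite.  Ties in the priority queue break on (distance,
    y, x), making the search order — and hence the result — reproducible.
    """
    if not seeds:
        raise EmptyWellError("multi_source_dijkstra requires at least one seed point")
    if weight_mode not in WEIGHT_MODES:
        raise ConfigError(
            f"unknown weight mode {weight_mode!r}; expected one of {WEIGHT_MODES}"
        )
    ys = np.array([p[1] for p in seeds.points], dtype=np.int64)
    xs = np.array([p[0] for p in seeds.points], dtype=np.int64)
    if ys.min() < 0 or ys.max() >= well.height or xs.min() < 0 or xs.max() >= well.width:
        raise ConfigError("seed point outside the well")
    mode = (
        _dijkstra.WEIGHT_MODE_SCALED
        if weight_mode == "scaled"
        else _dijkstra.WEIGHT_MODE_CLAMPED
    )
    dist = dijkstra_grid(well.intensities, ys, xs, mode)
    return DistanceMap(distances=dist, source=seeds)


def likelihood(
    dist: DistanceMap, norm_max: float, exponent: float = 1.0
) -> LikelihoodMap:
    """Convert a distance map into the root-likelihood map.

    ``L = (1 - dist / norm_max) ** exponent`` clamped into [0, 1]; L equals
    1 at seed points and decreases with path cost.  ``norm_max`` should be
    at least the maximum observed distance (see
    :func:`theoretical_norm_max`); larger distances clamp to L = 0.
    """
    if norm_max <= 0:
        raise ConfigError(f"norm_max must be positive, got {norm_max}")
    if exponent <= 0:
        raise ConfigError(f"exponent must be positive, got {exponent}")
    L = np.clip(1.0 - dist.distances / norm_max, 0.0, 1.0)
    if exponent != 1.0:
        L = L**exponent
    return LikelihoodMap(L=L, norm_max=float(norm_max), exponent=float(exponent))


def theoretical_norm_max(
    height: int,
    width: int,
    mode: str = "theoretical",
    observed_maxima: Sequence[float] | None = None,
) -> float:
    """Normalisation constant for the likelihood map.

    Mode ``"theoretical"`` (default) returns ``height + width``: every pixel
    is reachable within H+W steps of weight at most 1, so this bounds any
    shortest-path cost and makes single-image processing deterministic.
    Mode ``"empirical"`` returns the mean of the per-well maximum distances
    observed in a first batch pass (``observed_maxima``).
    """
    if height <= 0 or width <= 0:
        raise ConfigError("well dimensions must be positive")
    if mode == "theoretical":
        return float(height + width)
    if mode == "empirical":
        if not observed_maxima:
            raise ConfigError("empirical norm_max requires observed per-well maxima")
        return float(np.mean(np.asarray(observed_maxima, dtype=np.float64)))
    raise ConfigError(
        f"unknown norm_max mode {mode!r}; expected 'theoretical' or 'empirical'"
    )
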