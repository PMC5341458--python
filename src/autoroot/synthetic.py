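"""Deterministic synthetic plate and top-down images with known ground truth.

No public image set accompanies the phenotyping protocol, so every stage of
the pipeline is exercised on generated data: bright curvilinear root systems
(a sinuous primary root plus oblique laterals) rendered onto a dark noisy
well, with a bright seed region inside the top strip, and top-down rosette
views as saturated discs on a white background.  All randomness flows from a
single integer seed, so any fixture is reproducible byte for byte.

Default geometry and intensities emulate the acquisition system the method
was designed for: wells of 290×710 px imaged against a dark agar background,
roots a few pixels wide and clearly brighter than the background, mild
sensor noise and sparse bright speckle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import ConfigError
from .well_image import WellGrid

__all__ = [
    "SyntheticRootSpec",
    "GroundTruth",
    "PopulationCondition",
    "CONTROL_CONDITION",
    "INHIBITED_CONDITION",
    "generate_root_well",
    "generate_plate",
    "generate_top_view",
    "generate_population",
    "generate_proxy_population",
]

#: Wavelength (px of depth) of the sinusoidal wander of the primary root.
_CURVE_WAVELENGTH = 300.0


@dataclass(frozen=True)
class SyntheticRootSpec:
    """Parameters of one synthetic root-system well.

    ``primary_length`` is the arc length of the primary root in pixels; the
    root starts inside the top seed strip and is truncated at the bottom row
    if it would leave the well.  ``curvature_amplitude`` is the lateral
    wander (px) of the sinuous primary axis.  Laterals branch from the
    primary below 20% of its depth at ``lateral_angle_range`` degrees from
    vertical.  Intensities are 8-bit; ``noise_sigma`` is additive Gaussian
    noise and ``salt_density`` the per-pixel probability of a bright speck
    at root intensity.  ``sharp`` disables the anti-aliased Gaussian stroke
    cross-section in favour of a binary stroke (for exact-mask tests).
    """

    width: int = 290
    height: int = 710
    primary_length: float = 400.0
    curvature_amplitude: float = 15.0
    n_laterals: int = 3
    lateral_angle_range: tuple[float, float] = (35.0, 65.0)
    lateral_length_range: tuple[float, float] = (50.0, 120.0)
    root_half_width: float = 2.0
    root_intensity: int = 200
    background_intensity: int = 20
    noise_sigma: float = 6.0
    salt_density: float = 5e-4
    seed: int = 0
    sharp: bool = False
    start_x: Optional[int] = None
    start_y: Optional[int] = None
    strip_fraction: float = 0.05

    def __post_init__(self):
        if self.root_intensity <= self.background_intensity:
            raise ConfigError("root intensity must exceed background intensity")
        strip = math.ceil(self.strip_fraction * self.height)
        y0 = self.start_y if self.start_y is not None else min(10, strip - 1)
        if not 0 <= y0 < strip:
            raise ConfigError(
                f"start_y={y0} outside the top strip (first {strip} rows)"
            )

    @property
    def origin(self) -> tuple[int, int]:
        """Start point (x, y) of the primary root, inside the top strip."""
        strip = math.ceil(self.strip_fraction * self.height)
        x0 = self.start_x if self.start_x is not None else self.width // 2
        y0 = self.start_y if self.start_y is not None else min(10, strip - 1)
        return x0, y0


@dataclass(frozen=True)
class GroundTruth:
    """Known truth for a generated image."""

    root_mask: Optional[np.ndarray] = None
    primary_length: float = 0.0
    lateral_count: int = 0
    max_depth: int = 0
    leaf_pixel_count: int = 0


def _stamp_offsets(half_width: float) -> np.ndarray:
    r = int(math.ceil(half_width))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy * dy + dx * dx <= half_width * half_width
    return np.stack([dy[keep], dx[keep]], axis=1)


def _paint_path(mask: np.ndarray, points: Sequence[tuple[float, float]], half_width: float) -> None:
    """Paint discs of the given radius along a polyline onto a boolean canvas."""
    H, W = mask.shape
    offsets = _stamp_offsets(half_width)
    for px, py in points:
        cy, cx = int(round(py)), int(round(px))
        ys = cy + offsets[:, 0]
        xs = cx + offsets[:, 1]
        ok = (ys >= 0) & (ys < H) & (xs >= 0) & (xs < W)
        mask[ys[ok], xs[ok]] = True


def _primary_path(
    spec: SyntheticRootSpec, phase: float
) -> tuple[list[tuple[float, float]], float]:
    """Sample the sinuous primary root at ~0.5 px arc-length resolution.

    Returns the point list and the arc length actually drawn (shorter than
    requested when the root reaches the bottom of the well).
    """
    x0, y0 = spec.origin
    pts: list[tuple[float, float]] = []
    arc = 0.0
    t = 0.0
    dt = 0.5
    a = spec.curvature_amplitude
    k = 2.0 * math.pi / _CURVE_WAVELENGTH

    def x_at(t_: float) -> float:
        return x0 + a * (math.sin(k * t_ + phase) - math.sin(phase))

    prev = (x_at(0.0), float(y0))
    pts.append(prev)
    while arc < spec.primary_length:
        t += dt
        y = y0 + t
        if y > spec.height - 1:
            break
        cur = (x_at(t), y)
        arc += math.hypot(cur[0] - prev[0], cur[1] - prev[1])
        pts.append(cur)
        prev = cur
    return pts, arc


def _lateral_paths(
    spec: SyntheticRootSpec,
    primary: list[tuple[float, float]],
    rng: np.random.Generator,
) -> list[list[tuple[float, float]]]:
    """Straight oblique laterals branching from the lower 80% of the primary."""
    if spec.n_laterals <= 0 or len(primary) < 10:
        return []
    laterals = []
    n_pts = len(primary)
    lo, hi = spec.lateral_angle_range
    for _ in range(spec.n_laterals):
        i = int(rng.uniform(0.2, 0.85) * n_pts)
        bx, by = primary[i]
        angle = math.radians(rng.uniform(lo, hi))
        side = 1.0 if rng.random() < 0.5 else -1.0
        length = rng.uniform(*spec.lateral_length_range)
        dx = side * math.sin(angle)
        dy = math.cos(angle)
        n_steps = max(int(length / 0.5), 2)
        path = []
        for s in range(n_steps + 1):
            px = bx + dx * s * 0.5
            py = by + dy * s * 0.5
            if not (0 <= px <= spec.width - 1 and 0 <= py <= spec.height - 1):
                break
            path.append((px, py))
        if len(path) >= 2:
            laterals.append(path)
    return laterals


def generate_root_well(spec: SyntheticRootSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic well image with its ground truth.

    The primary root descends from a bright seed blob inside the top strip,
    wandering sinusoidally with the configured amplitude; laterals branch
    obliquely from its lower part.  Strokes are painted at the root
    intensity with either a soft (Gaussian) or sharp (binary) cross-section,
    then Gaussian noise and bright salt speckle are added.  The ground-truth
    mask records the pre-noise rendered pixels; the true primary length is
    the arc length actually drawn (truncation at the bottom row shortens
    roots longer than the well).
    """
    rng = np.random.default_rng(spec.seed)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    H, W = spec.height, spec.width

    primary, drawn = _primary_path(spec, phase)
    laterals = _lateral_paths(spec, primary, rng)

    mask = np.zeros((H, W), dtype=bool)
    _paint_path(mask, primary, spec.root_half_width)
    for path in laterals:
        _paint_path(mask, path, max(1.0, 0.6 * spec.root_half_width))
    # bright seed blob at the origin, inside the strip
    x0, y0 = spec.origin
    _paint_path(mask, [(float(x0), float(y0))], spec.root_half_width + 1.5)

    bg = float(spec.background_intensity)
    amplitude = float(spec.root_intensity) - bg
    if spec.sharp:
        profile = mask.astype(np.float64)
    else:
        profile = ndimage.gaussian_filter(mask.astype(np.float64), sigma=spec.root_half_width / 2.0)
        peak = profile.max()
        if peak > 0:
            profile = np.clip(profile / peak, 0.0, 1.0)
    clean = np.rint(bg + amplitude * profile).astype(np.uint8)
    truth_mask = clean != np.uint8(round(bg))

    img = clean.astype(np.float64)
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    if spec.salt_density > 0:
        salt = rng.random(img.shape) < spec.salt_density
        img[salt] = float(spec.root_intensity)
    img = np.rint(np.clip(img, 0, 255)).astype(np.uint8)

    ys = np.nonzero(truth_mask.any(axis=1))[0]
    max_depth = int(ys.max()) if ys.size else 0
    truth = GroundTruth(
        root_mask=truth_mask,
        primary_length=drawn,
        lateral_count=len(laterals),
        max_depth=max_depth,
    )
    return img, truth


def generate_plate(
    specs: Sequence[SyntheticRootSpec],
    grid: WellGrid,
    plate_intensity: int = 60,
    canvas_shape: tuple[int, int] | None = None,
) -> tuple[np.ndarray, list[GroundTruth]]:
    """Composite per-well images into a plate canvas at the grid rectangles.

    The canvas (plate frame between and around wells) renders at
    ``plate_intensity``.  Returns the plate image and the per-well ground
    truths in grid order.
    """
    if len(specs) != grid.n_wells:
        raise ConfigError(
            f"{len(specs)} specs supplied for a grid of {grid.n_wells} wells"
        )
    max_x = max(x + w for x, _, w, _ in grid.well_rects)
    max_y = max(y + h for _, y, _, h in grid.well_rects)
    if canvas_shape is None:
        min_x = min(x for x, _, _, _ in grid.well_rects)
        min_y = min(y for _, y, _, _ in grid.well_rects)
        canvas_shape = (max_y + min_y, max_x + min_x)
    if canvas_shape[0] < max_y or canvas_shape[1] < max_x:
        raise ConfigError("canvas too small for the well grid")
    plate = np.full(canvas_shape, plate_intensity, dtype=np.uint8)
    truths = []
    for spec, (rx, ry, rw, rh) in zip(specs, grid.well_rects):
        if (spec.width, spec.height) != (rw, rh):
            raise ConfigError(
                f"spec well size {(spec.width, spec.height)} does not match "
                f"grid rectangle size {(rw, rh)}"
            )
        well, truth = generate_root_well(spec)
        plate[ry : ry + rh, rx : rx + rw] = well
        truths.append(truth)
    return plate, truths


def generate_top_view(
    leaf_count: int,
    radius_range: tuple[float, float] = (6.0, 14.0),
    hue: float = 120.0,
    seed: int = 0,
    size: tuple[int, int] = (140, 140),
) -> tuple[np.ndarray, GroundTruth]:
    """Top-down rosette stand-in: saturated discs of one hue on white.

    ``hue`` is in degrees.  The truth leaf-pixel count equals the rendered
    non-white pixel count exactly (discs are painted without anti-aliasing).
    """
    lo, hi = radius_range
    if lo <= 0 or hi < lo:
        raise ConfigError(f"invalid radius range {radius_range}")
    rng = np.random.default_rng(seed)
    H, W = size
    mask = np.zeros((H, W), dtype=bool)
    margin = int(math.ceil(hi)) + 1
    for _ in range(leaf_count):
        r = rng.uniform(lo, hi)
        cy = rng.uniform(margin, H - margin)
        cx = rng.uniform(margin, W - margin)
        yy, xx = np.mgrid[0:H, 0:W]
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    from matplotlib.colors import hsv_to_rgb

    rgb = hsv_to_rgb([(hue % 360.0) / 360.0, 0.85, 0.75])
    colour = np.rint(np.asarray(rgb) * 255.0).astype(np.uint8)
    img = np.full((H, W, 3), 255, dtype=np.uint8)
    img[mask] = colour
    truth = GroundTruth(leaf_pixel_count=int(mask.sum()))
    return img, truth


@dataclass(frozen=True)
class PopulationCondition:
    """Sampling distributions for one experimental condition."""

    name: str
    length_range: tuple[float, float]
    laterals_range: tuple[int, int]  # inclusive
    curvature_range: tuple[float, float] = (5.0, 25.0)


#: Untreated seedlings: long primaries, well-developed laterals.
CONTROL_CONDITION = PopulationCondition(
    name="control", length_range=(350.0, 650.0), laterals_range=(2, 7)
)
#: Growth-inhibited seedlings (emulating an osmotic-stress treatment):
#: stochastically shorter primaries and fewer laterals.
INHIBITED_CONDITION = PopulationCondition(
    name="inhibited", length_range=(120.0, 320.0), laterals_range=(0, 3)
)

_CONDITIONS = {"control": CONTROL_CONDITION, "inhibited": INHIBITED_CONDITION}


def _sample_spec(
    rng: np.random.Generator,
    length_range: tuple[float, float],
    laterals_range: tuple[int, int],
    curvature_range: tuple[float, float],
    base: SyntheticRootSpec,
) -> SyntheticRootSpec:
    return replace(
        base,
        primary_length=float(rng.uniform(*length_range)),
        n_laterals=int(rng.integers(laterals_range[0], laterals_range[1] + 1)),
        curvature_amplitude=float(rng.uniform(*curvature_range)),
        start_x=int(rng.integers(int(0.3 * base.width), int(0.7 * base.width))),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_population(
    n_wells: int,
    condition: Literal["control", "inhibited"] | PopulationCondition,
    seed: int = 0,
    base_spec: SyntheticRootSpec = SyntheticRootSpec(),
) -> list[tuple[SyntheticRootSpec, np.ndarray, GroundTruth]]:
    """Sample a reproducible population of wells under one condition."""
    if n_wells < 1:
        raise ConfigError("n_wells must be at least 1")
    cond = _CONDITIONS.get(condition) if isinstance(condition, str) else condition
    if cond is None:
        raise ConfigError(
            f"unknown condition {condition!r}; expected one of {sorted(_CONDITIONS)}"
        )
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_wells):
        spec = _sample_spec(
            rng, cond.length_range, cond.laterals_range, cond.curvature_range, base_spec
        )
        img, truth = generate_root_well(spec)
        out.append((spec, img, truth))
    return out


def generate_proxy_population(
    n_wells: int,
    seed: int = 0,
    length_range: tuple[float, float] = (100.0, 600.0),
    laterals_range: tuple[int, int] = (0, 8),
    base_spec: SyntheticRootSpec = SyntheticRootSpec(),
) -> list[tuple[SyntheticRootSpec, np.ndarray, GroundTruth]]:
    """Wells spanning a uniform range of true primary lengths.

    The series used to check that proxy traits recover known root geometry:
    lengths are uniform over ``length_range`` and lateral counts uniform
    over ``laterals_range``, with the generator's default moderate noise.
    """
    if n_wells < 1:
        raise ConfigError("n_wells must be at least 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_wells):
        spec = _sample_spec(
            rng, length_range, laterals_range, (5.0, 25.0), base_spec
        )
        img, truth = generate_root_well(spec)
        out.append((spec, img, truth))
    return out
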