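"""Unattended batch processing: images in, one traits CSV out.

The pipeline composes the stages — load, grayscale, contrast stretch, well
extraction, seed detection, multi-source shortest paths, likelihood map,
trait extraction (plus shoot traits when a paired top-down image exists) —
for every well of every image matching the input glob.  It never prompts,
and a failure on one image is logged and quarantined so the rest of the
batch completes.  Wells with no detectable seed points yield flagged
all-zero records rather than aborting.

With ``norm_max_mode: empirical`` the batch runs twice: a first pass
collects each well's maximum shortest-path distance, whose mean becomes the
shared likelihood normalisation constant for the second pass.
"""

from __future__ import annotations

import glob as _glob
import logging
import math
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import AutoRootError
from .likelihood import (
    DistanceMap,
    LikelihoodMap,
    detect_seed_points,
    likelihood,
    multi_source_dijkstra,
    theoretical_norm_max,
)
from .shoot import leaf_area, leaf_hue, leaf_mask
from .traits import TraitRecord, compute_traits
from .well_image import (
    GrayWell,
    contrast_stretch,
    extract_wells,
    load_plate_image,
    to_grayscale,
)

__all__ = [
    "BatchSummary",
    "process_image",
    "run_batch",
    "well_distance_map",
    "analyse_well",
    "analyse_well_images",
]

log = logging.getLogger("autoroot")


@dataclass
class BatchSummary:
    """Outcome counts for one batch run."""

    images_processed: int = 0
    images_failed: int = 0
    wells: int = 0
    empty_wells: int = 0
    failed_paths: list[str] = field(default_factory=list)
    output_csv: Optional[Path] = None


def well_distance_map(
    well: GrayWell,
    strip_fraction: float = 0.05,
    min_intensity: float = 0.2,
    weight_mode: str = "clamped",
) -> Optional[DistanceMap]:
    """Seed detection plus multi-source Dijkstra; None for an empty well."""
    seeds = detect_seed_points(well, strip_fraction, min_intensity)
    if not seeds:
        return None
    return multi_source_dijkstra(well, seeds, weight_mode=weight_mode)


def analyse_well(
    well: GrayWell,
    strip_fraction: float = 0.05,
    min_intensity: float = 0.2,
    norm_max: Optional[float] = None,
    exponent: float = 1.0,
    weight_mode: str = "clamped",
    image_id: str = "",
) -> tuple[TraitRecord, Optional[LikelihoodMap]]:
    """Full single-well analysis.

    ``norm_max`` defaults to the theoretical bound height + width of the
    well; pass the batch-empirical constant for two-pass runs.  Returns the
    trait record and the likelihood map (None when the well is empty).
    """
    dist = well_distance_map(well, strip_fraction, min_intensity, weight_mode)
    if dist is None:
        return TraitRecord.empty(image_id, well.well_index), None
    if norm_max is None:
        norm_max = theoretical_norm_max(well.height, well.width)
    lmap = likelihood(dist, norm_max, exponent)
    record = compute_traits(lmap, well, image_id=image_id)
    return record, lmap


def analyse_well_images(
    images: Sequence[np.ndarray],
    stretch: "StretchBounds" = None,
    strip_fraction: float = 0.05,
    min_intensity: float = 0.2,
    norm_max_mode: str = "empirical",
    exponent: float = 1.0,
    weight_mode: str = "clamped",
) -> list[TraitRecord]:
    """Analyse a sequence of single-well 8-bit images held in memory.

    The array counterpart of :func:`run_batch` for wells that never touch
    disk (generated populations, notebook experiments).  With the default
    ``norm_max_mode="empirical"`` the likelihood normalisation constant is
    the mean of the per-well maximum shortest-path distances over the whole
    series — the batch-calibrated normalisation — computed in a first pass;
    ``"theoretical"`` uses each well's height + width bound instead.
    """
    from .well_image import StretchBounds as _SB

    if stretch is None:
        stretch = _SB(40, 190)
    wells = []
    for i, img in enumerate(images):
        arr = np.asarray(img)
        if arr.ndim == 3:
            arr = to_grayscale(arr)
        wells.append(
            GrayWell(contrast_stretch(arr, stretch).astype(np.float64) / 255.0, well_index=i)
        )
    dists = [
        well_distance_map(w, strip_fraction, min_intensity, weight_mode) for w in wells
    ]
    records = []
    if norm_max_mode == "empirical":
        maxima = [d.max for d in dists if d is not None]
        if not maxima:
            raise AutoRootError("empirical normalisation found no non-empty wells")
        shared = float(np.mean(maxima))
        norms = [shared] * len(wells)
    else:
        norms = [theoretical_norm_max(w.height, w.width) for w in wells]
    for well, dist, norm in zip(wells, dists, norms):
        if dist is None:
            records.append(TraitRecord.empty("", well.well_index))
            continue
        lmap = likelihood(dist, norm, exponent)
        records.append(compute_traits(lmap, well))
    return records


def _shoot_traits_for(
    config: RunConfig, side_path: Path, n_wells: int
) -> list[tuple[Optional[int], Optional[float]]]:
    """Leaf area and hue per well from the paired top image, if any."""
    blank: list[tuple[Optional[int], Optional[float]]] = [(None, None)] * n_wells
    if config.top is None:
        return blank
    top_path = config.top.paired_path(side_path)
    if top_path is None:
        return blank
    try:
        top_img = load_plate_image(top_path)
    except (IOError, AutoRootError) as exc:
        log.warning("top image %s unreadable (%s); shoot traits skipped", top_path, exc)
        return blank
    config.top.grid.validate_for(top_img.shape[:2])
    out = []
    for rx, ry, rw, rh in config.top.grid.well_rects:
        region = top_img[ry : ry + rh, rx : rx + rw]
        mask = leaf_mask(region)
        out.append((leaf_area(mask), leaf_hue(region, mask)))
    if len(out) < n_wells:
        out += [(None, None)] * (n_wells - len(out))
    return out[:n_wells]


def _save_heatmap(lmap: LikelihoodMap, path: Path) -> None:
    """Render the likelihood map as an 8-bit heat-map PNG."""
    import imageio.v3 as iio
    from matplotlib import colormaps

    rgba = colormaps["inferno"](lmap.L)
    iio.imwrite(path, (rgba[:, :, :3] * 255).astype(np.uint8))


def process_image(
    path: str | Path,
    config: RunConfig,
    norm_max: Optional[float] = None,
) -> list[TraitRecord]:
    """Process one plate image into per-well trait records.

    ``norm_max`` overrides the per-well theoretical normalisation (used by
    the empirical two-pass batch).  Raises on an unreadable image; the batch
    driver catches and quarantines such failures.
    """
    path = Path(path)
    img = load_plate_image(path)
    gray = contrast_stretch(to_grayscale(img), config.stretch)
    wells = extract_wells(gray, config.side_grid)
    shoot = _shoot_traits_for(config, path, len(wells))
    records = []
    for well, (area, hue) in zip(wells, shoot):
        record, lmap = analyse_well(
            well,
            strip_fraction=config.side_grid.strip_fraction,
            min_intensity=config.seed_min_intensity,
            norm_max=norm_max,
            exponent=config.exponent,
            weight_mode=config.weight_mode,
            image_id=path.name,
        )
        record.leaf_area = area
        record.leaf_hue = hue
        if lmap is not None and config.heatmap_dir is not None:
            config.heatmap_dir.mkdir(parents=True, exist_ok=True)
            _save_heatmap(
                lmap, config.heatmap_dir / f"{path.stem}_well{well.well_index}.png"
            )
        records.append(record)
    return records


def _empirical_norm_max(files: Sequence[Path], config: RunConfig) -> float:
    """First pass of an empirical-normalisation batch: mean per-well max distance."""
    maxima = []
    for path in files:
        try:
            img = load_plate_image(path)
        except (IOError, AutoRootError):
            continue
        gray = contrast_stretch(to_grayscale(img), config.stretch)
        wells = extract_wells(gray, config.side_grid)
        for well in wells:
            dist = well_distance_map(
                well,
                config.side_grid.strip_fraction,
                config.seed_min_intensity,
                config.weight_mode,
            )
            if dist is not None:
                maxima.append(dist.max)
    if not maxima:
        raise AutoRootError("empirical normalisation found no non-empty wells")
    return float(np.mean(maxima))


def run_batch(config: RunConfig) -> BatchSummary:
    """Process every image matching the input glob and write the traits CSV.

    Inputs are processed in lexicographic filename order; per-image output
    is independent of that order.  The CSV is written atomically (temporary
    file, then rename), so reruns on identical inputs are byte-identical
    and a crash never leaves a half-written table.
    """
    files = sorted(Path(p) for p in _glob.glob(config.input))
    if not files:
        raise AutoRootError(f"no input files match {config.input!r}")
    norm_max = None
    if config.norm_max_mode == "empirical":
        norm_max = _empirical_norm_max(files, config)
        log.info("empirical norm_max over batch: %.3f", norm_max)
    summary = BatchSummary()
    rows = []
    for path in files:
        try:
            records = process_image(path, config, norm_max=norm_max)
        except (IOError, AutoRootError, ValueError) as exc:
            log.error("skipping %s: %s", path, exc)
            summary.images_failed += 1
            summary.failed_paths.append(str(path))
            continue
        summary.images_processed += 1
        summary.wells += len(records)
        summary.empty_wells += sum(r.empty_flag for r in records)
        rows.extend(r.to_dict() for r in records)
        log.info("%s: %d wells (%d empty)", path.name,
                 len(records), sum(r.empty_flag for r in records))
    frame = pd.DataFrame(rows, columns=TraitRecord.columns())
    out = Path(config.output_csv)
    out.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=out.parent, suffix=".csv.tmp")
    try:
        with os.fdopen(fd, "w", newline="") as fh:
            frame.to_csv(fh, index=False, lineterminator="\r\n")
        os.replace(tmp, out)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    summary.output_csv = out
    log.info(
        "batch done: %d images (%d failed), %d wells (%d empty) -> %s",
        summary.images_processed, summary.images_failed,
        summary.wells, summary.empty_wells, out,
    )
    return summary
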