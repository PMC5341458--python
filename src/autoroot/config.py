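"""Run configuration for unattended batch processing.

A batch is described by one YAML file (all keys optional except ``input``):

.. code-block:: yaml

    input: "plates/*.png"        # glob of side-view plate images
    output_csv: "traits.csv"
    side_grid:                   # either a uniform grid ...
      n_wells: 8
      well_width: 290
      well_height: 710
      x0: 10
      y0: 10
      gap: 10
      strip_fraction: 0.05
    # ... or explicit rectangles:
    # side_grid: {rects: [[10, 10, 290, 710], ...], strip_fraction: 0.05}
    stretch: {low: 40, high: 190}
    seed_min_intensity: 0.2
    exponent: 1.0
    norm_max_mode: theoretical   # or "empirical" (two-pass batch)
    weight_mode: clamped         # or "scaled"
    top:                         # optional top-down shoot imaging
      dir: "tops"
      suffix: "_top"
      grid: {n_wells: 8, well_width: 140, well_height: 140, x0: 0, y0: 0}
    heatmap_dir: null            # write per-well likelihood heat maps here
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigError
from .well_image import StretchBounds, WellGrid
from .likelihood import DEFAULT_MIN_SEED_INTENSITY

__all__ = ["RunConfig", "TopViewConfig"]


def _grid_from_dict(d: dict) -> WellGrid:
    if "rects" in d:
        return WellGrid(d["rects"], strip_fraction=d.get("strip_fraction", 0.05))
    try:
        return WellGrid.uniform(
            n_wells=d["n_wells"],
            well_width=d["well_width"],
            well_height=d["well_height"],
            x0=d.get("x0", 0),
            y0=d.get("y0", 0),
            gap=d.get("gap", 0),
            strip_fraction=d.get("strip_fraction", 0.05),
        )
    except KeyError as exc:
        raise ConfigError(f"grid definition missing key {exc}") from exc


@dataclass(frozen=True)
class TopViewConfig:
    """Where to find top-down images and how they pair with side images.

    A side image ``plate_001.png`` pairs with ``<dir>/plate_001<suffix>.<ext>``
    for any of the supported extensions.
    """

    directory: Path
    grid: WellGrid
    suffix: str = "_top"

    def paired_path(self, side_path: Path) -> Optional[Path]:
        stem = side_path.stem + self.suffix
        for ext in (".png", ".tif", ".tiff", ".jpg", ".jpeg"):
            cand = self.directory / (stem + ext)
            if cand.exists():
                return cand
        return None


@dataclass(frozen=True)
class RunConfig:
    """Everything a batch run needs; see the module docstring for the YAML form."""

    input: str
    side_grid: WellGrid
    output_csv: Path = Path("traits.csv")
    stretch: StretchBounds = StretchBounds(0, 255)
    seed_min_intensity: float = DEFAULT_MIN_SEED_INTENSITY
    exponent: float = 1.0
    norm_max_mode: str = "theoretical"
    weight_mode: str = "clamped"
    top: Optional[TopViewConfig] = None
    heatmap_dir: Optional[Path] = None

    def __post_init__(self):
        if self.norm_max_mode not in ("theoretical", "empirical"):
            raise ConfigError(
                f"norm_max_mode must be 'theoretical' or 'empirical', got {self.norm_max_mode!r}"
            )
        if self.weight_mode not in ("clamped", "scaled"):
            raise ConfigError(
                f"weight_mode must be 'clamped' or 'scaled', got {self.weight_mode!r}"
            )
        if self.exponent <= 0:
            raise ConfigError(f"exponent must be positive, got {self.exponent}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        path = Path(path)
        try:
            raw = yaml.safe_load(path.read_text())
        except OSError as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} is not a mapping")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(raw, base_dir=path.parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path = Path(".")) -> "RunConfig":
        if "input" not in raw:
            raise ConfigError("config requires an 'input' glob")
        if "side_grid" not in raw:
            raise ConfigError("config requires a 'side_grid' definition")
        stretch_d = raw.get("stretch", {"low": 0, "high": 255})
        top = None
        if raw.get("top"):
            t = raw["top"]
            top = TopViewConfig(
                directory=base_dir / t["dir"],
                grid=_grid_from_dict(t["grid"]),
                suffix=t.get("suffix", "_top"),
            )
        inp = raw["input"]
        input_glob = inp if Path(inp).is_absolute() else str(base_dir / inp)
        out = Path(raw.get("output_csv", "traits.csv"))
        heat = raw.get("heatmap_dir")
        return cls(
            input=input_glob,
            side_grid=_grid_from_dict(raw["side_grid"]),
            output_csv=out if out.is_absolute() else base_dir / out,
            stretch=StretchBounds(int(stretch_d["low"]), int(stretch_d["high"])),
            seed_min_intensity=float(
                raw.get("seed_min_intensity", DEFAULT_MIN_SEED_INTENSITY)
            ),
            exponent=float(raw.get("exponent", 1.0)),
            norm_max_mode=raw.get("norm_max_mode", "theoretical"),
            weight_mode=raw.get("weight_mode", "clamped"),
            top=top,
            heatmap_dir=(base_dir / heat) if heat else None,
        )
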