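"""Pipeline configuration: defaults, validation, TOML/YAML loading.

Defaults reproduce the acquisition and analysis constants of the study
design the pipeline targets: 848 x 480 frames, a top-view camera 2.25 m
above the floor, a 14-day training window and 1-4 day forecast horizons.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from pigmorph.errors import ConfigError


@dataclass
class PipelineConfig:
    # image geometry
    image_width: int = 848
    image_height: int = 480
    camera_height_m: float = 2.25

    # RGB segmentation
    threshold_method: str = "otsu"  # "otsu" or "fixed"
    threshold_value: float | None = None  # required when method == "fixed"
    opening_diameter_px: int = 15
    border_margin_px: int = 2
    min_area_frac: float = 0.01
    max_area_frac: float = 0.40

    # depth / height
    centroid_window_px: int = 2
    estimate_floor_per_video: bool = False
    kmeans_restarts: int = 10
    merge_tol_m: float = 0.05

    # forecasting
    window_days: int = 14
    horizons: tuple[int, ...] = (1, 2, 3, 4)
    r2_definition: str = "squared_correlation"  # or "one_minus_sse_sst"

    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        errors = []
        if self.image_width <= 0 or self.image_height <= 0:
            errors.append("image dimensions must be positive")
        if self.camera_height_m <= 0:
            errors.append("camera_height_m must be positive")
        if self.threshold_method not in ("otsu", "fixed"):
            errors.append(f"unknown threshold_method {self.threshold_method!r}")
        if self.threshold_method == "fixed" and self.threshold_value is None:
            errors.append("threshold_value required when threshold_method='fixed'")
        if self.opening_diameter_px < 1:
            errors.append("opening_diameter_px must be >= 1")
        if self.border_margin_px < 0:
            errors.append("border_margin_px must be >= 0")
        if not (0 <= self.min_area_frac < self.max_area_frac <= 1):
            errors.append("area fractions must satisfy 0 <= min < max <= 1")
        if self.centroid_window_px < 0:
            errors.append("centroid_window_px must be >= 0")
        if self.kmeans_restarts < 1:
            errors.append("kmeans_restarts must be >= 1")
        if self.merge_tol_m < 0:
            errors.append("merge_tol_m must be >= 0")
        if self.window_days < 2:
            errors.append("window_days must be >= 2")
        self.horizons = tuple(int(h) for h in self.horizons)
        if not self.horizons or any(h < 1 for h in self.horizons):
            errors.append("horizons must be positive integers")
        if self.r2_definition not in ("squared_correlation", "one_minus_sse_sst"):
            errors.append(f"unknown r2_definition {self.r2_definition!r}")
        if errors:
            raise ConfigError("; ".join(errors))


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a TOML or YAML config file; missing file section keys keep
    their defaults, unknown keys are rejected with an explicit message."""
    if path is None:
        return PipelineConfig()
    path = Path(path)
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    elif path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    else:
        raise ConfigError(f"unsupported config format: {path.suffix!r} (use .toml/.yaml)")
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a table/mapping, got {type(raw).__name__}")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
    try:
        return PipelineConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Write the config as YAML so that ``load_config`` round-trips it."""
    data = dataclasses.asdict(cfg)
    data["horizons"] = list(cfg.horizons)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
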