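"""Shared dataclasses for frames, measurements and boxes.

Coordinate convention throughout the package: ``x`` is the column index,
``y`` the row index, origin at the top-left pixel, 0-based.  Lengths and
widths are floating-point pixels; heights and depths are metres once they
leave the raw 16-bit depth map (which stores millimetres, 0 = invalid).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class QCStatus(str, Enum):
    """Per-frame quality-control verdict."""

    OK = "OK"
    NO_OBJECT = "NO_OBJECT"
    BORDER_ATTACHED = "BORDER_ATTACHED"
    AREA_OUT_OF_RANGE = "AREA_OUT_OF_RANGE"
    INVALID_DEPTH = "INVALID_DEPTH"


@dataclass
class FramePair:
    """One RGB frame with its aligned metric depth map.

    ``depth_mm`` is a uint16 grid of millimetres from the camera; a value
    of 0 marks an invalid reading.  ``depth_mm`` may be ``None`` for
    RGB-only records (the height stage is then skipped).
    """

    rgb: np.ndarray
    depth_mm: np.ndarray | None
    frame_index: int = 0

    def __post_init__(self) -> None:
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError(f"rgb must be H x W x 3, got shape {self.rgb.shape}")
        if self.depth_mm is not None and self.depth_mm.shape != self.rgb.shape[:2]:
            raise ValueError(
                f"depth shape {self.depth_mm.shape} does not match "
                f"rgb shape {self.rgb.shape[:2]}"
            )


@dataclass
class SegmentationResult:
    """Binary mask of the single largest foreground component.

    ``contour`` is an ordered (N, 2) array of (x, y) boundary points.
    """

    mask: np.ndarray
    area_px: int
    contour: np.ndarray


@dataclass
class RotatedBoundingBox:
    """Minimum-area rectangle enclosing a contour, at arbitrary angle.

    ``angle`` is in degrees; ``corners`` is a (4, 2) array of (x, y)
    vertices in order around the rectangle.
    """

    center: tuple[float, float]
    side_a: float
    side_b: float
    angle: float
    corners: np.ndarray


@dataclass
class FrameMeasurement:
    """Length/width of one frame, or the QC reason it was discarded.

    ``length_px``/``width_px`` are present iff ``qc`` is OK, and then
    ``length_px >= width_px``.
    """

    frame_index: int
    qc: QCStatus
    length_px: float | None = None
    width_px: float | None = None


@dataclass
class HeightMeasurement:
    """Height of the animal in one depth frame."""

    frame_index: int
    qc: QCStatus
    centroid: tuple[int, int] | None = None
    centroid_depth_m: float | None = None
    height_m: float | None = None


@dataclass
class PostureClustering:
    """Two-cluster (standing vs sitting) split of per-frame heights."""

    labels: np.ndarray
    cluster_medians: tuple[float, float]
    standing_cluster: int
    merged: bool


@dataclass
class LMMFit:
    """Random-intercept linear mixed model fit.

    ``beta`` holds (intercept, length, width, height) fixed effects;
    ``animal_effects`` maps animal id to its predicted random intercept
    (BLUP, kg) for every animal in the training window.
    """

    beta: np.ndarray
    sigma2_animal: float
    sigma2_resid: float
    animal_effects: dict
    training_keys: set = field(default_factory=set)
    converged: bool = True
    beta_se: np.ndarray | None = None


@dataclass
class CVScenario:
    """One forecast horizon of the sliding-window cross-validation."""

    window_days: int
    horizon: int
    slide_starts: list


@dataclass
class ForecastResult:
    """Per-slide prediction accuracy for one (model, horizon) pair."""

    model: str
    horizon: int
    per_slide: list  # of (start_day, r2, mae_kg, n_test)

    @property
    def r2_values(self) -> np.ndarray:
        return np.array([s[1] for s in self.per_slide], dtype=float)

    @property
    def mae_values(self) -> np.ndarray:
        return np.array([s[2] for s in self.per_slide], dtype=float)

    def summary(self) -> dict:
        r2 = self.r2_values
        return {
            "model": self.model,
            "horizon": self.horizon,
            "n_slides": len(self.per_slide),
            "r2_min": float(np.min(r2)) if r2.size else float("nan"),
            "r2_median": float(np.median(r2)) if r2.size else float("nan"),
            "r2_max": float(np.max(r2)) if r2.size else float("nan"),
            "mae_median": float(np.median(self.mae_values)) if r2.size else float("nan"),
        }
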