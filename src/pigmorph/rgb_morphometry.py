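"""Body length and width from top-view RGB frames.

Pipeline per frame: grayscale conversion -> global threshold (Otsu by
default) -> largest connected component -> morphological opening (removes
the tail) -> contour -> minimum-area rotated bounding box -> QC filters
(border attachment, then pixel-count range).  Per video, the medians of
the surviving frames' lengths and widths give the final estimates, so a
minority of distorted or motion-blurred frames cannot pull the result.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
import shapely
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.morphology import isotropic_opening

from pigmorph.config import PipelineConfig
from pigmorph.errors import DegenerateContourError, NoObjectError, NoValidFramesError
from pigmorph.types import (
    FrameMeasurement,
    FramePair,
    QCStatus,
    RotatedBoundingBox,
    SegmentationResult,
)

logger = logging.getLogger(__name__)

_EIGHT_CONN = np.ones((3, 3), dtype=int)


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to 8-bit grayscale (ITU-R 601 luma)."""
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 input, got shape {rgb.shape}")
    weights = np.array([0.299, 0.587, 0.114])
    gray = rgb.astype(np.float64) @ weights
    return np.clip(np.round(gray), 0, 255).astype(np.uint8)


def _largest_component(binary: np.ndarray) -> tuple[np.ndarray, int]:
    """Largest 8-connected foreground component and its area.

    Ties on equal area are broken by the smallest top-left bounding
    coordinate (row-major order of the first labelled pixel, which
    ``ndimage.label`` assigns in scan order).
    """
    labels, n = ndimage.label(binary, structure=_EIGHT_CONN)
    if n == 0:
        return np.zeros_like(binary, dtype=bool), 0
    counts = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(counts)) + 1  # argmax takes the first (scan-order) max
    return labels == best, int(counts[best - 1])


def segment_largest(gray: np.ndarray, cfg: PipelineConfig | None = None) -> SegmentationResult:
    """Threshold, keep the largest blob, open away thin protrusions.

    The binarization polarity (animal lighter or darker than the floor)
    is chosen automatically: the pen floor dominates the image border,
    so the threshold class holding the majority of border pixels is
    background and the other class is the animal.  After the opening
    (Euclidean-disk structuring element, diameter
    ``cfg.opening_diameter_px``) the largest component is re-extracted
    and its boundary contour returned as (x, y) points.

    Raises :class:`NoObjectError` when no foreground survives.
    """
    if cfg is None:
        cfg = PipelineConfig()
    if gray.ndim != 2:
        raise ValueError(f"expected a single-channel image, got shape {gray.shape}")

    if cfg.threshold_method == "fixed":
        t = cfg.threshold_value
    else:
        if np.all(gray == gray.flat[0]):
            raise NoObjectError("uniform image, no threshold separates an object")
        t = threshold_otsu(gray)

    above = gray > t
    border = np.concatenate([above[0], above[-1], above[:, 0], above[:, -1]])
    foreground = ~above if border.mean() >= 0.5 else above
    mask, area = _largest_component(foreground)
    if area == 0:
        raise NoObjectError("no foreground component on the animal side of the threshold")

    # Open within the blob's bounding window only; the Euclidean-disk
    # opening (distance-transform based) matches an explicit disk
    # structuring element of the same radius.
    radius = max(1, cfg.opening_diameter_px // 2)
    sl_y, sl_x = ndimage.find_objects(mask.astype(np.uint8))[0]
    pad = radius + 2
    y0 = max(0, sl_y.start - pad)
    y1 = min(gray.shape[0], sl_y.stop + pad)
    x0 = max(0, sl_x.start - pad)
    x1 = min(gray.shape[1], sl_x.stop + pad)
    opened = isotropic_opening(mask[y0:y1, x0:x1], radius)
    crop, area = _largest_component(opened)
    if area == 0:
        raise NoObjectError("opening removed all foreground")
    mask = np.zeros_like(mask)
    mask[y0:y1, x0:x1] = crop

    contours = measure.find_contours(crop.astype(float), 0.5)
    contour_rc = max(contours, key=len)  # (row, col) points
    contour_xy = contour_rc[:, ::-1] + np.array([x0, y0], dtype=float)
    return SegmentationResult(mask=mask, area_px=area, contour=contour_xy)


def rotated_box(contour: np.ndarray) -> RotatedBoundingBox:
    """Minimum-area rotated rectangle enclosing the contour points.

    ``contour`` is an (N, 2) array of (x, y) points, N >= 3; collinear
    input raises :class:`DegenerateContourError`.
    """
    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or contour.shape[1] != 2 or len(contour) < 3:
        raise DegenerateContourError(f"need >= 3 (x, y) points, got shape {contour.shape}")
    rect = shapely.multipoints(contour).minimum_rotated_rectangle
    if rect.geom_type != "Polygon":
        raise DegenerateContourError("contour is degenerate (collinear or coincident points)")
    corners = np.array(rect.exterior.coords[:4], dtype=float)
    e1 = corners[1] - corners[0]
    e2 = corners[2] - corners[1]
    side_a = float(np.linalg.norm(e1))
    side_b = float(np.linalg.norm(e2))
    if side_a == 0 or side_b == 0:
        raise DegenerateContourError("degenerate rectangle with a zero-length side")
    angle = float(np.degrees(np.arctan2(e1[1], e1[0])) % 180.0)
    center = tuple(np.mean(corners, axis=0))
    return RotatedBoundingBox(
        center=(float(center[0]), float(center[1])),
        side_a=side_a,
        side_b=side_b,
        angle=angle,
        corners=corners,
    )


def canonical_length_width(box: RotatedBoundingBox) -> tuple[float, float]:
    """Order the box sides as (length, width), length >= width."""
    return max(box.side_a, box.side_b), min(box.side_a, box.side_b)


def border_attached(
    box: RotatedBoundingBox, image_dims: tuple[int, int], margin_px: int = 2
) -> bool:
    """True iff any box corner is within ``margin_px`` of an image edge
    (or outside the image).  ``image_dims`` is (height, width)."""
    H, W = image_dims
    x, y = box.corners[:, 0], box.corners[:, 1]
    return bool(
        np.any(x <= margin_px)
        or np.any(y <= margin_px)
        or np.any(x >= W - 1 - margin_px)
        or np.any(y >= H - 1 - margin_px)
    )


def area_in_range(
    area_px: int,
    min_frac: float,
    max_frac: float,
    image_dims: tuple[int, int],
) -> bool:
    """True iff the blob covers between ``min_frac`` and ``max_frac`` of
    the frame.  Frames outside the range likely hold severe shape
    distortion or motion blur."""
    if not (0 <= min_frac < max_frac <= 1):
        raise ValueError("require 0 <= min_frac < max_frac <= 1")
    H, W = image_dims
    total = H * W
    return min_frac * total <= area_px <= max_frac * total


def measure_frame(frame: FramePair, cfg: PipelineConfig | None = None) -> FrameMeasurement:
    """Measure one frame: segmentation, rotated box and the QC chain
    (border attachment first, then pixel-count range)."""
    if cfg is None:
        cfg = PipelineConfig()
    dims = frame.rgb.shape[:2]
    try:
        gray = to_grayscale(frame.rgb)
        seg = segment_largest(gray, cfg)
        box = rotated_box(seg.contour)
    except (NoObjectError, DegenerateContourError):
        return FrameMeasurement(frame_index=frame.frame_index, qc=QCStatus.NO_OBJECT)

    if border_attached(box, dims, cfg.border_margin_px):
        return FrameMeasurement(frame_index=frame.frame_index, qc=QCStatus.BORDER_ATTACHED)
    if not area_in_range(seg.area_px, cfg.min_area_frac, cfg.max_area_frac, dims):
        return FrameMeasurement(frame_index=frame.frame_index, qc=QCStatus.AREA_OUT_OF_RANGE)

    length, width = canonical_length_width(box)
    return FrameMeasurement(
        frame_index=frame.frame_index,
        qc=QCStatus.OK,
        length_px=length,
        width_px=width,
    )


def aggregate_length_width(
    measurements: list[FrameMeasurement],
) -> tuple[float, float, int]:
    """Median length and width over the QC-passing frames of a video.

    Returns ``(median_length_px, median_width_px, n_used)``; raises
    :class:`NoValidFramesError` if every frame failed QC.
    """
    ok = [m for m in measurements if m.qc is QCStatus.OK]
    if not ok:
        raise NoValidFramesError("no frame passed quality control")
    lengths = np.array([m.length_px for m in ok])
    widths = np.array([m.width_px for m in ok])
    return float(np.median(lengths)), float(np.median(widths)), len(ok)
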