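"""Body height from top-view depth frames.

Per frame: segment the animal in the depth rendering, find the mask
centroid, read the median depth in a small window around it, and
subtract from the camera-to-floor distance (2.25 m by default).  Because
a freely moving animal alternates between standing and sitting, the
per-frame heights of a video are split with two-cluster k-means; the
cluster with the higher median is taken as standing and its median is
the video's height estimate.

Two segmentation inputs are supported: the hue channel of a colorized
depth rendering (vendor viewers export these), or a raw metric depth map
normalized to 8 bits.  Both feed the same threshold/largest-component
segmentation as the RGB path.
"""

from __future__ import annotations

import logging

import numpy as np
from skimage import color
from sklearn.cluster import KMeans

from pigmorph.config import PipelineConfig
from pigmorph.errors import InvalidDepthError, NoObjectError, NoValidFramesError
from pigmorph.rgb_morphometry import segment_largest
from pigmorph.types import FramePair, HeightMeasurement, PostureClustering, QCStatus

logger = logging.getLogger(__name__)


def depth_to_hue(image: np.ndarray, cfg: PipelineConfig | None = None) -> np.ndarray:
    """Reduce a depth rendering to one 8-bit channel for segmentation.

    A 3-channel input is treated as a colorized depth image and its HSV
    hue channel is returned.  A 2-D input is treated as a raw metric
    depth map and min-max normalized to 8 bits (the fallback path when
    no colorized rendering exists).
    """
    if image.ndim == 3 and image.shape[2] == 3:
        hue = color.rgb2hsv(image)[..., 0]  # in [0, 1)
        return np.clip(np.round(hue * 255.0), 0, 255).astype(np.uint8)
    if image.ndim == 2:
        depth = image.astype(np.float64)
        valid = depth > 0
        if not np.any(valid):
            return np.zeros(image.shape, dtype=np.uint8)
        lo, hi = depth[valid].min(), depth[valid].max()
        if hi == lo:
            return np.where(valid, 128, 0).astype(np.uint8)
        norm = np.zeros_like(depth)
        norm[valid] = (depth[valid] - lo) / (hi - lo) * 255.0
        return np.clip(np.round(norm), 0, 255).astype(np.uint8)
    raise ValueError(f"expected a 2-D depth map or H x W x 3 rendering, got {image.shape}")


def centroid_of_mask(mask: np.ndarray) -> tuple[int, int]:
    """Area centroid (first moments / area) rounded half-up to the
    nearest pixel, as (x, y)."""
    ys, xs = np.nonzero(mask)
    if len(xs) == 0:
        raise NoObjectError("empty mask has no centroid")
    cx = float(np.mean(xs))
    cy = float(np.mean(ys))
    return int(np.floor(cx + 0.5)), int(np.floor(cy + 0.5))


def sample_centroid_depth(
    depth_mm: np.ndarray, centroid: tuple[int, int], window_px: int = 2
) -> float:
    """Median valid depth (metres) in a (2w+1)^2 window at the centroid.

    Zero pixels are invalid sensor readings and are ignored; if the
    whole window is invalid, :class:`InvalidDepthError` is raised.
    """
    H, W = depth_mm.shape
    x, y = centroid
    if not (0 <= x < W and 0 <= y < H):
        raise InvalidDepthError(f"centroid {centroid} outside {W}x{H} depth map")
    w = window_px
    patch = depth_mm[max(0, y - w) : y + w + 1, max(0, x - w) : x + w + 1]
    valid = patch[patch > 0]
    if valid.size == 0:
        raise InvalidDepthError("all depth pixels around the centroid are invalid (0)")
    return float(np.median(valid)) / 1000.0


def height_from_depth(centroid_depth_m: float, camera_height_m: float) -> float:
    """Animal height = camera-to-floor distance minus camera-to-back
    distance.  A non-positive result means the reading lies at or below
    the floor and raises :class:`InvalidDepthError`."""
    h = camera_height_m - centroid_depth_m
    if h <= 0:
        raise InvalidDepthError(
            f"centroid depth {centroid_depth_m} m at or beyond the floor "
            f"({camera_height_m} m)"
        )
    return h


def estimate_floor_depth(depth_mm: np.ndarray, mask: np.ndarray) -> float:
    """Per-frame floor distance in metres: median valid depth outside
    the animal mask."""
    outside = depth_mm[(~mask) & (depth_mm > 0)]
    if outside.size == 0:
        raise InvalidDepthError("no valid floor pixels outside the mask")
    return float(np.median(outside)) / 1000.0


def measure_height(frame: FramePair, cfg: PipelineConfig | None = None) -> HeightMeasurement:
    """Height of one frame via segmentation -> centroid -> depth lookup
    -> subtraction."""
    if cfg is None:
        cfg = PipelineConfig()
    if frame.depth_mm is None:
        return HeightMeasurement(frame_index=frame.frame_index, qc=QCStatus.INVALID_DEPTH)
    try:
        channel = depth_to_hue(frame.depth_mm, cfg)
        seg = segment_largest(channel, cfg)
        centroid = centroid_of_mask(seg.mask)
        depth_m = sample_centroid_depth(frame.depth_mm, centroid, cfg.centroid_window_px)
        if cfg.estimate_floor_per_video:
            camera_h = estimate_floor_depth(frame.depth_mm, seg.mask)
        else:
            camera_h = cfg.camera_height_m
        h = height_from_depth(depth_m, camera_h)
    except NoObjectError:
        return HeightMeasurement(frame_index=frame.frame_index, qc=QCStatus.NO_OBJECT)
    except InvalidDepthError:
        return HeightMeasurement(frame_index=frame.frame_index, qc=QCStatus.INVALID_DEPTH)
    return HeightMeasurement(
        frame_index=frame.frame_index,
        qc=QCStatus.OK,
        centroid=centroid,
        centroid_depth_m=depth_m,
        height_m=h,
    )


def cluster_postures(
    heights,
    seed: int = 0,
    n_restarts: int = 10,
    merge_tol: float = 0.05,
) -> PostureClustering:
    """Two-cluster k-means on per-frame heights (metres).

    The higher-median cluster is labelled standing.  If the cluster
    means differ by less than ``merge_tol`` (an animal that never sat,
    or never stood), the split is spurious and all frames are merged
    into one cluster.  Fewer than two heights also yield a merged,
    single-cluster result.
    """
    h = np.asarray(list(heights), dtype=float)
    if h.size < 2 or np.ptp(h) == 0.0:
        med = float(np.median(h)) if h.size else float("nan")
        return PostureClustering(
            labels=np.zeros(h.size, dtype=int),
            cluster_medians=(med, med),
            standing_cluster=0,
            merged=True,
        )
    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed & 0x7FFFFFFF)
    labels = km.fit_predict(h.reshape(-1, 1))
    means = km.cluster_centers_.ravel()
    if abs(means[0] - means[1]) < merge_tol:
        med = float(np.median(h))
        return PostureClustering(
            labels=np.zeros(h.size, dtype=int),
            cluster_medians=(med, med),
            standing_cluster=0,
            merged=True,
        )
    medians = tuple(float(np.median(h[labels == k])) for k in (0, 1))
    return PostureClustering(
        labels=labels,
        cluster_medians=medians,
        standing_cluster=int(np.argmax(medians)),
        merged=False,
    )


def video_height(
    frames: list[FramePair],
    cfg: PipelineConfig | None = None,
    seed: int = 0,
) -> tuple[float, int, bool]:
    """Single height estimate for a video: the median of the standing
    cluster of the per-frame heights.

    Returns ``(height_m, n_used, merged)``; raises
    :class:`NoValidFramesError` when no frame yields a height.
    """
    if cfg is None:
        cfg = PipelineConfig()
    if not frames:
        raise NoValidFramesError("empty video")
    heights = []
    for frame in frames:
        m = measure_height(frame, cfg)
        if m.qc is QCStatus.OK:
            heights.append(m.height_m)
    if not heights:
        raise NoValidFramesError("no frame yielded a valid height")
    clustering = cluster_postures(
        heights, seed=seed, n_restarts=cfg.kmeans_restarts, merge_tol=cfg.merge_tol_m
    )
    h = np.asarray(heights)
    if clustering.merged:
        est = float(np.median(h))
    else:
        est = float(clustering.cluster_medians[clustering.standing_cluster])
    return est, len(heights), clustering.merged
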