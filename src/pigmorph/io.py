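"""Dataset layout and PNG/CSV readers and writers.

On disk a dataset is laid out as::

    <root>/<pig_id>/<day>/frame_0000.png   8-bit RGB
                          depth_0000.png   16-bit grayscale, millimetres
                          truth.csv        optional ground truth
    <root>/weights.csv                     pig_id, day, weight_kg

Depth is stored losslessly as 16-bit PNG in millimetres (0 = invalid),
the standard interchange for consumer depth sensors once vendor bag
files have been converted.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np
import pandas as pd

from pigmorph.types import FramePair

logger = logging.getLogger(__name__)

_FRAME_RE = re.compile(r"frame_(\d+)\.png$")


def write_rgb_png(path: str | Path, rgb: np.ndarray) -> None:
    iio.imwrite(path, rgb.astype(np.uint8))


def write_depth_png(path: str | Path, depth_mm: np.ndarray) -> None:
    iio.imwrite(path, depth_mm.astype(np.uint16))


def read_rgb_png(path: str | Path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    return img[..., :3].astype(np.uint8)


def read_depth_png(path: str | Path) -> np.ndarray:
    return iio.imread(path).astype(np.uint16)


def write_video(
    video_dir: str | Path,
    frames: list[FramePair],
    truths: pd.DataFrame | None = None,
) -> None:
    """Write one video's frame pairs (and optional truth table)."""
    video_dir = Path(video_dir)
    video_dir.mkdir(parents=True, exist_ok=True)
    for pair in frames:
        write_rgb_png(video_dir / f"frame_{pair.frame_index:04d}.png", pair.rgb)
        if pair.depth_mm is not None:
            write_depth_png(video_dir / f"depth_{pair.frame_index:04d}.png", pair.depth_mm)
    if truths is not None:
        truths.to_csv(video_dir / "truth.csv", index=False)


def read_video(video_dir: str | Path) -> list[FramePair]:
    """Read one video directory into frame pairs, sorted by index.

    A frame with RGB but no matching depth file yields an RGB-only pair
    (the height stage skips it with a warning).  Unreadable files are
    logged and skipped.  Depth files without RGB raise.
    """
    video_dir = Path(video_dir)
    rgb_paths = {}
    for p in sorted(video_dir.glob("frame_*.png")):
        m = _FRAME_RE.search(p.name)
        if m:
            rgb_paths[int(m.group(1))] = p
    depth_paths = {
        int(p.stem.split("_")[1]): p for p in sorted(video_dir.glob("depth_*.png"))
    }
    orphans = sorted(set(depth_paths) - set(rgb_paths))
    if orphans and not rgb_paths:
        raise FileNotFoundError(
            f"{video_dir}: depth frames {orphans[:5]} have no matching RGB "
            f"(expected frame_%04d.png)"
        )
    frames = []
    for idx in sorted(rgb_paths):
        try:
            rgb = read_rgb_png(rgb_paths[idx])
        except Exception as exc:  # noqa: BLE001 - corrupt file isolation
            logger.warning("skipping unreadable frame %s: %s", rgb_paths[idx], exc)
            continue
        depth = None
        if idx in depth_paths:
            try:
                depth = read_depth_png(depth_paths[idx])
            except Exception as exc:  # noqa: BLE001
                logger.warning("depth unreadable for frame %d (%s); RGB only", idx, exc)
        else:
            logger.warning("no depth map for frame %d in %s", idx, video_dir)
        frames.append(FramePair(rgb=rgb, depth_mm=depth, frame_index=idx))
    return frames


def read_dataset(root: str | Path) -> Iterator[tuple[str, int, list[FramePair]]]:
    """Lazily yield ``(pig_id, day, frames)`` in sorted order."""
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} is not a directory")
    pig_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    found = False
    for pig_dir in pig_dirs:
        day_dirs = sorted(
            (d for d in pig_dir.iterdir() if d.is_dir() and d.name.isdigit()),
            key=lambda d: int(d.name),
        )
        for day_dir in day_dirs:
            frames = read_video(day_dir)
            if frames:
                found = True
                yield pig_dir.name, int(day_dir.name), frames
    if not found:
        raise FileNotFoundError(f"no video frames found under {root}")


def read_weights(path: str | Path) -> pd.DataFrame:
    """Read the scale-weight table (pig_id, day, weight_kg)."""
    df = pd.read_csv(path)
    missing = {"pig_id", "day", "weight_kg"} - set(df.columns)
    if missing:
        raise ValueError(f"weights file {path} missing columns: {sorted(missing)}")
    df["pig_id"] = df["pig_id"].astype(str)
    df["day"] = df["day"].astype(int)
    return df
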