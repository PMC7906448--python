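"""End-to-end composition: dataset -> descriptors -> table -> forecasts.

``run_pipeline`` processes every video of a dataset through the RGB and
depth measurement stages, joins the per-video descriptors with the scale
weights, computes the descriptor/weight correlation matrix, runs the
sliding-window forecast cross-validation, and writes every product plus
a reproducibility manifest to the output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from pigmorph import __version__
from pigmorph.config import PipelineConfig
from pigmorph.depth_morphometry import video_height
from pigmorph.descriptor_assembly import join_records, pearson_matrix
from pigmorph.errors import NoValidFramesError
from pigmorph.io import read_dataset, read_weights
from pigmorph.rgb_morphometry import aggregate_length_width, measure_frame
from pigmorph.types import QCStatus
from pigmorph.weight_forecasting import make_scenarios, results_frame, run_cv

logger = logging.getLogger(__name__)


def measure_dataset(
    root: str | Path, cfg: PipelineConfig, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Measure every video under ``root``.

    Returns ``(per_frame, per_video)``: per-frame length/width rows with
    their QC verdicts, and per-video descriptor medians.  Videos where
    every frame fails QC (or the height stage fails) are logged and
    omitted from the per-video table.
    """
    frame_rows = []
    video_rows = []
    for pig_id, day, frames in read_dataset(root):
        measurements = [measure_frame(f, cfg) for f in frames]
        for m in measurements:
            frame_rows.append(
                (pig_id, day, m.frame_index, m.length_px, m.width_px, m.qc.value)
            )
        try:
            length, width, n_used = aggregate_length_width(measurements)
        except NoValidFramesError:
            logger.warning("pig %s day %d: no frame passed RGB QC; video dropped", pig_id, day)
            continue
        has_depth = [f for f in frames if f.depth_mm is not None]
        if not has_depth:
            logger.warning("pig %s day %d: no depth maps; height skipped", pig_id, day)
            continue
        try:
            height, n_height, merged = video_height(has_depth, cfg, seed=seed)
        except NoValidFramesError:
            logger.warning("pig %s day %d: no valid height; video dropped", pig_id, day)
            continue
        video_rows.append((pig_id, day, length, width, height, n_used, n_height, merged))
    per_frame = pd.DataFrame(
        frame_rows, columns=["pig_id", "day", "frame", "length_px", "width_px", "qc"]
    )
    per_video = pd.DataFrame(
        video_rows,
        columns=[
            "pig_id",
            "day",
            "length_px",
            "width_px",
            "height_m",
            "n_frames_lw",
            "n_frames_height",
            "posture_merged",
        ],
    )
    return per_frame, per_video


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(
    root: str | Path,
    cfg: PipelineConfig | None = None,
    out_dir: str | Path = "results",
    seed: int = 0,
) -> Path:
    """Run measurement, assembly and forecasting on a dataset.

    Expects ``<root>/weights.csv`` beside the per-pig video directories.
    Writes measurements.csv, heights within descriptors.csv, table.csv,
    correlations.csv, forecast_slides.csv, forecast_summary.json and
    manifest.json under ``out_dir``; returns that path.
    """
    if cfg is None:
        cfg = PipelineConfig()
    root = Path(root)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    per_frame, per_video = measure_dataset(root, cfg, seed=seed)
    per_frame.to_csv(out_dir / "measurements.csv", index=False, float_format="%.6f")
    per_video.to_csv(out_dir / "descriptors.csv", index=False, float_format="%.6f")

    weights = read_weights(root / "weights.csv")
    table = join_records(per_video, weights)
    table.to_csv(out_dir / "table.csv", index=False, float_format="%.6f")

    corr = pearson_matrix(table)
    corr.to_csv(out_dir / "correlations.csv", float_format="%.6f")

    scenarios = make_scenarios(table["day"].unique(), window=cfg.window_days, horizons=cfg.horizons)
    results = run_cv(table, scenarios, r2_definition=cfg.r2_definition)
    results_frame(results).to_csv(out_dir / "forecast_slides.csv", index=False, float_format="%.6f")
    with open(out_dir / "forecast_summary.json", "w") as fh:
        json.dump([r.summary() for r in results], fh, indent=2)

    manifest = {
        "pigmorph_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": dataclasses.asdict(cfg),
        "config_hash": _config_hash(cfg),
        "seed": seed,
        "dataset_root": str(root),
        "n_videos": int(len(per_video)),
        "n_frames": int(len(per_frame)),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out_dir
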