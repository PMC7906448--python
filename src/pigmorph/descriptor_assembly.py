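"""Join per-video descriptors with scale weights; correlation analysis.

Units are kept exactly as measured — pixels for length and width, metres
for height — so the derived volume proxy is in px^2·m.  No pixel-to-cm
calibration is attempted.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DESCRIPTOR_COLUMNS = ["weight_kg", "length_px", "width_px", "height_m", "volume"]


def compute_volume(length_px: float, width_px: float, height_m: float) -> float:
    """Volume proxy: the product length x width x height (px^2·m)."""
    if length_px <= 0 or width_px <= 0 or height_m <= 0:
        raise ValueError("volume requires positive length, width and height")
    return length_px * width_px * height_m


def _check_unique(df: pd.DataFrame, name: str) -> None:
    dup = df.duplicated(subset=["pig_id", "day"])
    if dup.any():
        keys = df.loc[dup, ["pig_id", "day"]].itertuples(index=False, name=None)
        raise ValueError(f"duplicate (pig_id, day) keys in {name}: {sorted(set(keys))}")


def join_records(descriptors: pd.DataFrame, weights: pd.DataFrame) -> pd.DataFrame:
    """Inner-join per-video descriptors with weight records on
    (pig_id, day).

    ``descriptors`` needs columns (pig_id, day, length_px, width_px,
    height_m); ``weights`` needs (pig_id, day, weight_kg).  Volume is
    (re)derived from the joined descriptors.  Unmatched keys on either
    side are logged; duplicate keys raise.
    """
    _check_unique(descriptors, "descriptors")
    _check_unique(weights, "weights")
    desc = descriptors.copy()
    desc["volume"] = desc["length_px"] * desc["width_px"] * desc["height_m"]
    merged = desc.merge(
        weights[["pig_id", "day", "weight_kg"]], on=["pig_id", "day"], how="inner"
    )
    d_keys = set(map(tuple, descriptors[["pig_id", "day"]].itertuples(index=False, name=None)))
    w_keys = set(map(tuple, weights[["pig_id", "day"]].itertuples(index=False, name=None)))
    for key in sorted(d_keys - w_keys):
        logger.warning("descriptor without weight record: %s", key)
    for key in sorted(w_keys - d_keys):
        logger.warning("weight record without descriptors: %s", key)
    if (merged["weight_kg"] <= 0).any():
        raise ValueError("non-positive weight in joined table")
    cols = ["pig_id", "day", "length_px", "width_px", "height_m", "volume", "weight_kg"]
    return merged[cols].sort_values(["pig_id", "day"]).reset_index(drop=True)


def pearson_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations between weight and the four image
    descriptors, pooled across all animal-days.

    Constant columns yield undefined (NaN) entries and a warning.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows for a correlation matrix")
    data = table[DESCRIPTOR_COLUMNS]
    constant = [c for c in DESCRIPTOR_COLUMNS if data[c].nunique() <= 1]
    if constant:
        warnings.warn(
            f"constant columns give undefined correlations: {constant}", stacklevel=2
        )
    corr = data.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    for c in constant:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
        corr.loc[c, c] = np.nan
    return corr
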