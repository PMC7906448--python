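"""Synthetic top-view RGB-D scenes and longitudinal growth data.

The study's raw videos are not deposited, so this module renders the
imagery the pipeline expects with known ground truth: a single animal
per frame, modelled as a rotated filled ellipse with a thin tail
protrusion, on a uniform pen floor seen from a ceiling camera.  The
depth map is metric (millimetres), with the body raised above the floor
by a tapering height profile.  A growth simulator produces multi-day
descriptor/weight tables following a random-intercept linear model, so
the forecasting stage can be tested against known parameters.

Frame mixtures (standing/sitting, border-touching, motion-blurred) mimic
the quality problems of freely moving animals that the pipeline's QC
filters are designed to reject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from pigmorph.types import FramePair

logger = logging.getLogger(__name__)

# Rendering constants.  The floor/body intensity gap is large so Otsu
# thresholding separates them cleanly; sitting compresses the body height
# to give k-means a well separated bimodal height distribution.
FLOOR_INTENSITY = 60
BODY_INTENSITY = 200
SITTING_HEIGHT_FACTOR = 0.55
EDGE_PROFILE = 0.7  # depth profile value at the body outline
CORE_RADIUS = 0.15  # normalized radius of the flat top of the back
TAIL_WIDTH_PX = 5
TAIL_LENGTH_PX = 25
BLUR_LENGTH_PX = 21


@dataclass
class SceneConfig:
    """Geometry and noise of the rendered scene.

    ``camera_height`` is metres from camera to floor; ``floor_depth_mm``
    is its millimetre equivalent and is derived automatically when left
    at None.  Fractions control the mixture of frame types emitted by
    :func:`simulate_video`.
    """

    image_width: int = 848
    image_height: int = 480
    camera_height: float = 2.25
    floor_depth_mm: int | None = None
    pig_length: float = 200.0
    pig_width: float = 80.0
    pig_height: float = 0.50
    standing_fraction: float = 0.7
    border_fraction: float = 0.0
    blur_fraction: float = 0.0
    depth_noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.floor_depth_mm is None:
            self.floor_depth_mm = round(1000 * self.camera_height)
        if not (self.pig_length >= self.pig_width > 0):
            raise ValueError("require pig_length >= pig_width > 0")
        if self.pig_height <= 0:
            raise ValueError("pig_height must be positive")
        for name in ("standing_fraction", "border_fraction", "blur_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.border_fraction + self.blur_fraction > 1:
            raise ValueError("border_fraction + blur_fraction must be <= 1")
        if self.depth_noise_sd < 0:
            raise ValueError("depth_noise_sd must be >= 0")


@dataclass
class FrameTruth:
    """Ground truth of one rendered frame.

    ``true_height`` is the standing height; a sitting frame is rendered
    at ``SITTING_HEIGHT_FACTOR * true_height``.
    """

    frame_index: int
    center: tuple[float, float]
    orientation: float  # degrees in [0, 180)
    posture: str  # "standing" | "sitting"
    touches_border: bool
    blurred: bool
    true_length: float
    true_width: float
    true_height: float

    def __post_init__(self) -> None:
        if self.true_length < self.true_width:
            raise ValueError("true_length must be >= true_width")
        if self.true_height <= 0:
            raise ValueError("true_height must be positive")
        if self.posture not in ("standing", "sitting"):
            raise ValueError(f"unknown posture {self.posture!r}")

    @property
    def rendered_height(self) -> float:
        """Height actually rendered into the depth map, in metres."""
        if self.posture == "sitting":
            return SITTING_HEIGHT_FACTOR * self.true_height
        return self.true_height


def _ellipse_extent(length: float, width: float, orientation_deg: float) -> tuple[float, float]:
    """Half-extent of the rotated ellipse along x and y."""
    a, b = length / 2.0, width / 2.0
    th = np.deg2rad(orientation_deg)
    ex = np.hypot(a * np.cos(th), b * np.sin(th))
    ey = np.hypot(a * np.sin(th), b * np.cos(th))
    return float(ex), float(ey)


def _body_masks(cfg: SceneConfig, truth: FrameTruth) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize the body.

    Returns ``(mask, radius)`` where ``mask`` is the boolean body mask
    (ellipse plus tail) and ``radius`` the normalized elliptical radius
    (0 at center, 1 at the outline; tail pixels are assigned radius 1 so
    they render at the outline height).
    """
    H, W = cfg.image_height, cfg.image_width
    cx, cy = truth.center
    a, b = truth.true_length / 2.0, truth.true_width / 2.0
    th = np.deg2rad(truth.orientation)
    cos_t, sin_t = np.cos(th), np.sin(th)

    # Work in a clipped bounding window for speed.
    pad = int(np.ceil(max(a, b) + TAIL_LENGTH_PX)) + 2
    x0, x1 = max(0, int(cx) - pad), min(W, int(cx) + pad + 1)
    y0, y1 = max(0, int(cy) - pad), min(H, int(cy) + pad + 1)
    if x0 >= x1 or y0 >= y1:
        return np.zeros((H, W), bool), np.zeros((H, W), float)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx, dy = xs - cx, ys - cy
    u = dx * cos_t + dy * sin_t  # along major axis
    v = -dx * sin_t + dy * cos_t  # along minor axis
    r2 = (u / a) ** 2 + (v / b) ** 2
    ellipse = r2 <= 1.0

    # Tail: a thin rectangle appended at the +u pole, removable by the
    # pipeline's morphological opening.
    tail = (u >= a - 1) & (u <= a + TAIL_LENGTH_PX) & (np.abs(v) <= TAIL_WIDTH_PX / 2.0)

    window = ellipse | tail
    radius = np.where(ellipse, np.sqrt(np.clip(r2, 0.0, 1.0)), 1.0)

    mask = np.zeros((H, W), bool)
    rad = np.zeros((H, W), float)
    mask[y0:y1, x0:x1] = window
    rad_win = np.where(window, radius, 0.0)
    rad[y0:y1, x0:x1] = rad_win
    return mask, rad


def _directional_blur(
    rgb: np.ndarray, orientation_deg: float, mask: np.ndarray
) -> np.ndarray:
    """Convolve each channel with a line kernel along the body axis.

    The floor is uniform, so only the window around the body changes;
    the convolution is restricted to it for speed.
    """
    n = BLUR_LENGTH_PX
    kern = np.zeros((n, n))
    c = n // 2
    th = np.deg2rad(orientation_deg)
    ts = np.linspace(-c, c, 4 * n)
    xs = np.clip(np.round(c + ts * np.cos(th)).astype(int), 0, n - 1)
    ys = np.clip(np.round(c + ts * np.sin(th)).astype(int), 0, n - 1)
    kern[ys, xs] = 1.0
    kern /= kern.sum()

    sl_y, sl_x = ndimage.find_objects(mask.astype(np.uint8))[0]
    H, W = mask.shape
    y0, y1 = max(0, sl_y.start - n), min(H, sl_y.stop + n)
    x0, x1 = max(0, sl_x.start - n), min(W, sl_x.stop + n)
    out = rgb.copy()
    for ch in range(3):
        win = rgb[y0:y1, x0:x1, ch].astype(float)
        out[y0:y1, x0:x1, ch] = np.clip(
            ndimage.convolve(win, kern, mode="nearest"), 0, 255
        ).astype(np.uint8)
    return out


def render_frame(
    cfg: SceneConfig, truth: FrameTruth, rng: np.random.Generator | None = None
) -> FramePair:
    """Render one RGB + depth frame pair from ground truth.

    The depth map equals ``floor_depth_mm`` on the floor and
    ``floor_depth_mm - round(1000 * h * profile)`` over the body, where
    the profile is 1 at the body center tapering linearly to
    ``EDGE_PROFILE`` at the outline, so the centroid depth recovers the
    rendered height exactly in the noiseless case.  Gaussian depth noise
    (sd ``cfg.depth_noise_sd`` mm, truncated at 4 sd) is added when
    requested; blurred frames get a directional blur on the RGB channel.
    """
    H, W = cfg.image_height, cfg.image_width
    cx, cy = truth.center
    if not (0 <= cx < W and 0 <= cy < H):
        raise ValueError(f"center {truth.center} outside {W}x{H} image")
    ex, ey = _ellipse_extent(truth.true_length, truth.true_width, truth.orientation)
    if not truth.touches_border:
        if cx - ex < 0 or cx + ex >= W or cy - ey < 0 or cy + ey >= H:
            raise ValueError(
                "ellipse does not fit inside the frame but touches_border is False"
            )

    mask, radius = _body_masks(cfg, truth)

    rgb = np.full((H, W, 3), FLOOR_INTENSITY, dtype=np.uint8)
    rgb[mask] = BODY_INTENSITY
    if truth.blurred and mask.any():
        rgb = _directional_blur(rgb, truth.orientation, mask)

    h_m = truth.rendered_height
    # Flat top over the central core (so a small centroid window reads
    # the full height) tapering linearly to EDGE_PROFILE at the outline.
    taper = np.clip((radius - CORE_RADIUS) / (1.0 - CORE_RADIUS), 0.0, 1.0)
    profile = 1.0 - (1.0 - EDGE_PROFILE) * taper
    depth = np.full((H, W), float(cfg.floor_depth_mm), dtype=np.float32)
    depth[mask] -= np.round(1000.0 * h_m * profile[mask]).astype(np.float32)
    if cfg.depth_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(cfg.rng_seed)
        noise = rng.standard_normal(depth.shape, dtype=np.float32)
        noise *= cfg.depth_noise_sd
        lim = 4.0 * cfg.depth_noise_sd
        np.clip(noise, -lim, lim, out=noise)
        depth += noise
    np.round(depth, out=depth)
    np.clip(depth, 0, 65535, out=depth)
    depth = depth.astype(np.uint16)

    return FramePair(rgb=rgb, depth_mm=depth, frame_index=truth.frame_index)


def simulate_video(
    cfg: SceneConfig, n_frames: int, seed: int | None = None
) -> tuple[list[FramePair], list[FrameTruth]]:
    """Draw ``n_frames`` i.i.d. frames for one video.

    Postures are standing with probability ``cfg.standing_fraction``;
    each frame is border-touching with probability ``cfg.border_fraction``
    or blurred with probability ``cfg.blur_fraction`` (mutually
    exclusive).  Positions and orientations are uniform.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    H, W = cfg.image_height, cfg.image_width

    frames: list[FramePair] = []
    truths: list[FrameTruth] = []
    for i in range(n_frames):
        orientation = float(rng.uniform(0.0, 180.0))
        posture = "standing" if rng.uniform() < cfg.standing_fraction else "sitting"
        u = rng.uniform()
        touches_border = u < cfg.border_fraction
        blurred = (not touches_border) and u < cfg.border_fraction + cfg.blur_fraction

        ex, ey = _ellipse_extent(cfg.pig_length, cfg.pig_width, orientation)
        margin = TAIL_LENGTH_PX + 3  # keep the tail interior too
        if touches_border:
            # Put the center close to a random edge so the ellipse
            # crosses it.
            edge = rng.integers(4)
            if edge == 0:  # left
                cx = float(rng.uniform(1.0, 0.8 * ex))
                cy = float(rng.uniform(ey, H - ey))
            elif edge == 1:  # right
                cx = float(W - 1 - rng.uniform(1.0, 0.8 * ex))
                cy = float(rng.uniform(ey, H - ey))
            elif edge == 2:  # top
                cx = float(rng.uniform(ex, W - ex))
                cy = float(rng.uniform(1.0, 0.8 * ey))
            else:  # bottom
                cx = float(rng.uniform(ex, W - ex))
                cy = float(H - 1 - rng.uniform(1.0, 0.8 * ey))
        else:
            lo_x, hi_x = ex + margin, W - ex - margin
            lo_y, hi_y = ey + margin, H - ey - margin
            if lo_x >= hi_x or lo_y >= hi_y:
                raise ValueError(
                    f"body of length {cfg.pig_length} px cannot fit interior "
                    f"to a {W}x{H} frame at orientation {orientation:.1f} deg"
                )
            cx = float(rng.uniform(lo_x, hi_x))
            cy = float(rng.uniform(lo_y, hi_y))

        truth = FrameTruth(
            frame_index=i,
            center=(cx, cy),
            orientation=orientation,
            posture=posture,
            touches_border=touches_border,
            blurred=blurred,
            true_length=cfg.pig_length,
            true_width=cfg.pig_width,
            true_height=cfg.pig_height,
        )
        truths.append(truth)
        frames.append(render_frame(cfg, truth, rng=rng))
    return frames, truths


@dataclass
class GrowthConfig:
    """Parameters of the longitudinal growth simulation.

    Weight follows ``y = beta0 + beta_L*L + beta_W*W + beta_H*H + a_i + e``
    with a per-animal random intercept ``a_i ~ N(0, sigma_animal^2)`` and
    residual ``e ~ N(0, sigma_resid^2)``.  Defaults emulate eight growers
    followed for 38 days, gaining roughly 0.6 kg/day from about 23 kg.
    """

    n_animals: int = 8
    n_days: int = 38
    beta0: float = -35.0
    beta_L: float = 0.22  # kg per px of body length
    beta_W: float = 0.18  # kg per px of body width
    beta_H: float = 40.0  # kg per m of body height
    sigma_animal: float = 5.0  # kg
    sigma_resid: float = 1.0  # kg
    # per-day descriptor increments: length px, width px, height m
    descriptor_growth_rates: tuple[float, float, float] = (1.5, 0.6, 0.004)
    # mean and sd of the day-1 descriptor values
    start_means: tuple[float, float, float] = (140.0, 60.0, 0.42)
    start_sds: tuple[float, float, float] = (12.0, 6.0, 0.025)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_animal < 0:
            raise ValueError("sigma_animal must be >= 0")
        if self.sigma_resid <= 0:
            raise ValueError("sigma_resid must be positive")
        if self.n_days < 15:
            raise ValueError(
                "n_days must be >= 15 (one 14-day window plus a forecast day)"
            )
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")


def simulate_growth(g: GrowthConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate the longitudinal descriptor + weight table.

    Returns one row per animal-day with columns
    (pig_id, day, length_px, width_px, height_m, volume, weight_kg),
    plus a dict of the true parameters (betas, variances, per-animal
    intercepts and starting sizes) for recovery tests.
    """
    rng = np.random.default_rng(g.rng_seed)
    days = np.arange(1, g.n_days + 1)
    rows = []
    intercepts = {}
    starts = {}
    for i in range(g.n_animals):
        pig = f"pig{i + 1:02d}"
        a_i = rng.normal(0.0, g.sigma_animal) if g.sigma_animal > 0 else 0.0
        intercepts[pig] = float(a_i)
        L0, W0, H0 = (
            rng.normal(m, s) for m, s in zip(g.start_means, g.start_sds)
        )
        starts[pig] = (float(L0), float(W0), float(H0))
        gL, gW, gH = g.descriptor_growth_rates
        for d in days:
            t = d - 1
            L, W, H = L0 + gL * t, W0 + gW * t, H0 + gH * t
            e = rng.normal(0.0, g.sigma_resid)
            y = g.beta0 + g.beta_L * L + g.beta_W * W + g.beta_H * H + a_i + e
            rows.append((pig, int(d), L, W, H, L * W * H, y))
    table = pd.DataFrame(
        rows,
        columns=[
            "pig_id",
            "day",
            "length_px",
            "width_px",
            "height_m",
            "volume",
            "weight_kg",
        ],
    )
    truth = {
        "beta": np.array([g.beta0, g.beta_L, g.beta_W, g.beta_H]),
        "sigma2_animal": g.sigma_animal**2,
        "sigma2_resid": g.sigma_resid**2,
        "animal_intercepts": intercepts,
        "start_sizes": starts,
    }
    return table, truth


def truths_frame(truths: list[FrameTruth]) -> pd.DataFrame:
    """Flatten frame truths to a table (one row per frame)."""
    return pd.DataFrame(
        [
            (
                t.frame_index,
                t.center[0],
                t.center[1],
                t.orientation,
                t.posture,
                t.touches_border,
                t.blurred,
                t.true_length,
                t.true_width,
                t.true_height,
            )
            for t in truths
        ],
        columns=[
            "frame_index",
            "center_x",
            "center_y",
            "orientation_deg",
            "posture",
            "touches_border",
            "blurred",
            "true_length_px",
            "true_width_px",
            "true_height_m",
        ],
    )


def simulate_dataset(
    root,
    scene: SceneConfig | None = None,
    growth: GrowthConfig | None = None,
    n_frames: int = 60,
    seed: int = 0,
) -> pd.DataFrame:
    """Write a full multi-animal, multi-day RGB-D dataset to disk.

    Body sizes per animal-day come from :func:`simulate_growth`; each
    video is rendered with those sizes and written under
    ``<root>/<pig>/<day>/`` alongside its truth table, with the scale
    weights in ``<root>/weights.csv``.  One master seed fans out into
    independent per-table and per-video sub-seeds.  Returns the
    longitudinal truth table.
    """
    from pathlib import Path

    from pigmorph.io import write_video

    if scene is None:
        scene = SceneConfig()
    if growth is None:
        growth = GrowthConfig()
    root = Path(root)
    ss = np.random.SeedSequence(seed)
    table_seed, video_root = ss.spawn(2)
    growth = dataclasses_replace_seed(growth, int(table_seed.generate_state(1)[0] % 2**31))
    table, _ = simulate_growth(growth)
    video_seeds = video_root.spawn(len(table))
    for (_, row), vseed in zip(table.iterrows(), video_seeds):
        day_scene = scene_for_day(
            scene,
            row["length_px"],
            row["width_px"],
            row["height_m"],
            seed=int(vseed.generate_state(1)[0] % 2**31),
        )
        frames, truths = simulate_video(day_scene, n_frames, seed=day_scene.rng_seed)
        write_video(root / row["pig_id"] / f"{int(row['day']):02d}", frames, truths_frame(truths))
    table[["pig_id", "day", "weight_kg"]].to_csv(root / "weights.csv", index=False)
    table.to_csv(root / "truth_table.csv", index=False)
    return table


def dataclasses_replace_seed(growth: GrowthConfig, seed: int) -> GrowthConfig:
    """Copy a growth config with a new seed."""
    import dataclasses

    return dataclasses.replace(growth, rng_seed=seed)


def scene_for_day(
    base: SceneConfig,
    length_px: float,
    width_px: float,
    height_m: float,
    seed: int,
) -> SceneConfig:
    """Derive a per-day scene config with the day's true body size."""
    return SceneConfig(
        image_width=base.image_width,
        image_height=base.image_height,
        camera_height=base.camera_height,
        pig_length=length_px,
        pig_width=width_px,
        pig_height=height_m,
        standing_fraction=base.standing_fraction,
        border_fraction=base.border_fraction,
        blur_fraction=base.blur_fraction,
        depth_noise_sd=base.depth_noise_sd,
        rng_seed=seed,
    )
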