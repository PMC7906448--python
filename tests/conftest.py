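import numpy as np
import pytest

from pigmorph.config import PipelineConfig
from pigmorph.synthetic_scene import FrameTruth, SceneConfig


@pytest.fixture
def pipeline_cfg():
    return PipelineConfig()


@pytest.fixture
def small_scene():
    """Quarter-resolution scene with a proportionally smaller animal;
    keeps image-heavy tests fast without changing any geometry ratio."""
    return SceneConfig(
        image_width=212,
        image_height=120,
        pig_length=50.0,
        pig_width=20.0,
        pig_height=0.5,
    )


@pytest.fixture
def default_scene():
    return SceneConfig()


def centered_truth(cfg: SceneConfig, orientation: float = 0.0, posture: str = "standing",
                   blurred: bool = False) -> FrameTruth:
    return FrameTruth(
        frame_index=0,
        center=(cfg.image_width / 2, cfg.image_height / 2),
        orientation=orientation,
        posture=posture,
        touches_border=False,
        blurred=blurred,
        true_length=cfg.pig_length,
        true_width=cfg.pig_width,
        true_height=cfg.pig_height,
    )


def random_blob_contour(rng: np.random.Generator, n_points: int = 50) -> np.ndarray:
    """Random convex-ish point cloud standing in for a body contour."""
    n = rng.integers(5, n_points + 1)
    pts = rng.uniform(0, 200, size=(n, 2))
    pts[:, 0] *= rng.uniform(0.5, 2.0)
    return pts
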