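"""Length/width extraction: segmentation, rotated box, QC, aggregation."""

import dataclasses

import numpy as np
import pytest

from pigmorph.config import PipelineConfig
from pigmorph.errors import DegenerateContourError, NoObjectError, NoValidFramesError
from pigmorph.rgb_morphometry import (
    aggregate_length_width,
    area_in_range,
    border_attached,
    canonical_length_width,
    measure_frame,
    rotated_box,
    segment_largest,
    to_grayscale,
)
from pigmorph.synthetic_scene import SceneConfig, render_frame, simulate_video
from pigmorph.types import FrameMeasurement, FramePair, QCStatus, RotatedBoundingBox
from tests.conftest import centered_truth, random_blob_contour


def calipers_min_area_rect(points: np.ndarray, step_deg: float = 0.1):
    """Brute-force minimum-area rectangle: rotate the point cloud over a
    fine angle grid, refined with the convex-hull edge directions (one
    rectangle side is always collinear with a hull edge, so including
    those angles makes the scan exact and tie-free).  Independent oracle
    for the rotated-box implementation."""
    from scipy.spatial import ConvexHull

    angles = list(np.arange(0.0, 90.0, step_deg))
    hull = points[ConvexHull(points).vertices]
    edges = np.diff(np.vstack([hull, hull[:1]]), axis=0)
    angles.extend(-np.degrees(np.arctan2(edges[:, 1], edges[:, 0])) % 90.0)
    best = None
    for ang in angles:
        th = np.deg2rad(ang)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        q = points @ rot.T
        w = q[:, 0].max() - q[:, 0].min()
        h = q[:, 1].max() - q[:, 1].min()
        if best is None or w * h < best[0]:
            best = (w * h, w, h)
    _, w, h = best
    return max(w, h), min(w, h)


def rect_contour(width: float, height: float, angle_deg: float = 0.0, n_per_side: int = 10):
    xs = np.linspace(0, width, n_per_side)
    ys = np.linspace(0, height, n_per_side)
    pts = np.concatenate(
        [
            np.stack([xs, np.zeros_like(xs)], axis=1),
            np.stack([xs, np.full_like(xs, height)], axis=1),
            np.stack([np.zeros_like(ys), ys], axis=1),
            np.stack([np.full_like(ys, width), ys], axis=1),
        ]
    )
    th = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return pts @ rot.T


class TestToGrayscale:
    @pytest.mark.parametrize(
        "value,expected", [((0, 0, 0), 0), ((255, 255, 255), 255), ((100, 100, 100), 100)]
    )
    def test_constant_frames(self, value, expected):
        rgb = np.empty((8, 8, 3), dtype=np.uint8)
        rgb[...] = value
        assert np.all(to_grayscale(rgb) == expected)

    def test_rejects_wrong_channel_count(self):
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((8, 8), dtype=np.uint8))


class TestSegmentLargest:
    def test_ellipse_area_recovered_and_tail_removed(self, default_scene, pipeline_cfg):
        truth = centered_truth(default_scene, orientation=0.0)
        pair = render_frame(default_scene, truth)
        seg = segment_largest(to_grayscale(pair.rgb), pipeline_cfg)
        oracle = np.pi * (truth.true_length / 2) * (truth.true_width / 2)
        assert seg.area_px == pytest.approx(oracle, rel=0.05)
        # tail pixels sit beyond the +x pole of the ellipse at 0 deg
        tail_x = int(truth.center[0] + truth.true_length / 2 + 5)
        assert not seg.mask[int(truth.center[1]), tail_x]

    def test_uniform_image_has_no_object(self, pipeline_cfg):
        with pytest.raises(NoObjectError):
            segment_largest(np.full((60, 80), 77, dtype=np.uint8), pipeline_cfg)

    def test_largest_of_two_blobs_kept(self, pipeline_cfg):
        gray = np.zeros((200, 300), dtype=np.uint8)
        gray[40:140, 30:80] = 200  # 100x50 = 5000 px
        gray[50:75, 200:220] = 200  # 25x20 = 500 px
        seg = segment_largest(gray, pipeline_cfg)
        assert seg.mask[90, 50]
        assert not seg.mask[60, 210]

    def test_dark_animal_on_light_floor_segmented(self, pipeline_cfg):
        # polarity must flip automatically
        gray = np.full((200, 300), 220, dtype=np.uint8)
        gray[40:140, 30:80] = 30
        seg = segment_largest(gray, pipeline_cfg)
        assert seg.mask[90, 50]
        assert seg.area_px == pytest.approx(5000, rel=0.1)


class TestRotatedBox:
    def test_axis_aligned_rectangle(self):
        box = rotated_box(rect_contour(100, 40))
        assert sorted([box.side_a, box.side_b]) == pytest.approx([40, 100], abs=1e-6)
        assert box.angle % 90 == pytest.approx(0, abs=1e-6)

    def test_rotated_rectangle_sides_within_one_px(self):
        box = rotated_box(rect_contour(100, 40, angle_deg=30))
        assert canonical_length_width(box) == pytest.approx((100, 40), abs=1.0)

    @pytest.mark.parametrize("angle", [0, 25, 60, 115, 170])
    def test_ellipse_contour_sides_near_axes(self, angle):
        t = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        th = np.deg2rad(angle)
        x = 100 * np.cos(t) * np.cos(th) - 40 * np.sin(t) * np.sin(th)
        y = 100 * np.cos(t) * np.sin(th) + 40 * np.sin(t) * np.cos(th)
        box = rotated_box(np.stack([x, y], axis=1))
        assert canonical_length_width(box) == pytest.approx((200, 80), abs=2.0)

    def test_agrees_with_calipers_oracle_on_random_contours(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            pts = random_blob_contour(rng)
            box = rotated_box(pts)
            oracle = calipers_min_area_rect(pts)
            assert canonical_length_width(box) == pytest.approx(oracle, abs=1.0)

    def test_collinear_contour_is_degenerate(self):
        pts = np.stack([np.arange(10.0), 2 * np.arange(10.0)], axis=1)
        with pytest.raises(DegenerateContourError):
            rotated_box(pts)


class TestQCPredicates:
    @pytest.mark.parametrize(
        "sides,expected", [((30, 80), (80, 30)), ((50, 50), (50, 50)), ((200.4, 79.6), (200.4, 79.6))]
    )
    def test_canonical_length_width(self, sides, expected):
        box = RotatedBoundingBox(
            center=(0, 0), side_a=sides[0], side_b=sides[1], angle=0.0,
            corners=np.zeros((4, 2)),
        )
        assert canonical_length_width(box) == expected

    def _box_at(self, corners):
        c = np.asarray(corners, dtype=float)
        return RotatedBoundingBox(
            center=tuple(c.mean(axis=0)), side_a=1, side_b=1, angle=0, corners=c
        )

    def test_interior_box_not_attached(self):
        box = self._box_at([(10, 10), (100, 10), (100, 60), (10, 60)])
        assert not border_attached(box, (480, 848), margin_px=2)

    @pytest.mark.parametrize("x0", [0, 1])
    def test_corner_near_left_edge_attached(self, x0):
        box = self._box_at([(x0, 50), (60, 50), (60, 90), (x0, 90)])
        assert border_attached(box, (480, 848), margin_px=2)

    def test_area_fraction_bounds(self):
        dims = (480, 848)
        assert area_in_range(8000, 0.01, 0.40, dims)
        assert not area_in_range(100, 0.01, 0.40, dims)
        assert not area_in_range(480 * 848, 0.01, 0.40, dims)


class TestMeasureFrame:
    def test_interior_standing_frame_measured_within_two_px(self, default_scene, pipeline_cfg):
        truth = centered_truth(default_scene, orientation=25.0)
        m = measure_frame(render_frame(default_scene, truth), pipeline_cfg)
        assert m.qc is QCStatus.OK
        assert m.length_px == pytest.approx(truth.true_length, abs=2.0)
        assert m.width_px == pytest.approx(truth.true_width, abs=2.0)

    def test_border_touching_frame_rejected(self, default_scene, pipeline_cfg):
        truth = centered_truth(default_scene)
        truth = dataclasses.replace(truth, center=(20.0, 240.0), touches_border=True)
        m = measure_frame(render_frame(default_scene, truth), pipeline_cfg)
        assert m.qc is QCStatus.BORDER_ATTACHED
        assert m.length_px is None

    def test_oversized_blob_out_of_area_range(self, pipeline_cfg):
        rgb = np.full((480, 848, 3), 60, dtype=np.uint8)
        rgb[65:415, 74:774] = 200  # 350x700 = 60% of the frame, interior
        m = measure_frame(FramePair(rgb=rgb, depth_mm=None), pipeline_cfg)
        assert m.qc is QCStatus.AREA_OUT_OF_RANGE

    def test_empty_pen_no_object(self, pipeline_cfg):
        rgb = np.full((120, 212, 3), 60, dtype=np.uint8)
        m = measure_frame(FramePair(rgb=rgb, depth_mm=None), pipeline_cfg)
        assert m.qc is QCStatus.NO_OBJECT


class TestAggregate:
    def _ok(self, i, length, width):
        return FrameMeasurement(frame_index=i, qc=QCStatus.OK, length_px=length, width_px=width)

    def test_median_robust_to_one_outlier(self):
        ms = [self._ok(0, 100, 40), self._ok(1, 101, 41), self._ok(2, 250, 90)]
        length, width, n = aggregate_length_width(ms)
        assert (length, n) == (101, 3)

    def test_single_ok_frame_identity(self):
        ms = [
            FrameMeasurement(frame_index=0, qc=QCStatus.BORDER_ATTACHED),
            self._ok(1, 120, 50),
        ]
        assert aggregate_length_width(ms) == (120, 50, 1)

    def test_all_rejected_raises(self):
        ms = [FrameMeasurement(frame_index=0, qc=QCStatus.NO_OBJECT)]
        with pytest.raises(NoValidFramesError):
            aggregate_length_width(ms)

    def test_contaminated_median_stays_within_clean_range(self):
        rng = np.random.default_rng(0)
        clean = [self._ok(i, 200 + rng.uniform(-1, 1), 80 + rng.uniform(-1, 1)) for i in range(30)]
        bad = [self._ok(100 + i, 400.0, 10.0) for i in range(10)]  # <50% contamination
        length, width, _ = aggregate_length_width(clean + bad)
        clean_lengths = [m.length_px for m in clean]
        assert min(clean_lengths) <= length <= max(clean_lengths)


class TestVideoLevelProperties:
    def test_rotation_invariance_of_measurements(self, default_scene, pipeline_cfg):
        lengths, widths = [], []
        for ang in range(0, 180, 10):
            truth = centered_truth(default_scene, orientation=float(ang))
            m = measure_frame(render_frame(default_scene, truth), pipeline_cfg)
            assert m.qc is QCStatus.OK
            lengths.append(m.length_px)
            widths.append(m.width_px)
        assert np.ptp(lengths) < 2.0
        assert np.ptp(widths) < 2.0

    def test_scale_equivariance(self, default_scene):
        cfg = PipelineConfig(min_area_frac=0.005)
        small = dataclasses.replace(default_scene, pig_length=100.0, pig_width=40.0)
        big = dataclasses.replace(default_scene, pig_length=200.0, pig_width=80.0)
        ms = measure_frame(render_frame(small, centered_truth(small, 20.0)), cfg)
        mb = measure_frame(render_frame(big, centered_truth(big, 20.0)), cfg)
        assert mb.length_px / ms.length_px == pytest.approx(2.0, rel=0.02)
        assert mb.width_px / ms.width_px == pytest.approx(2.0, rel=0.02)

    def test_qc_soundness_on_synthetic_video(self, default_scene, pipeline_cfg):
        cfg = dataclasses.replace(default_scene, border_fraction=0.3, blur_fraction=0.0)
        frames, truths = simulate_video(cfg, 40, seed=13)
        for pair, truth in zip(frames, truths):
            m = measure_frame(pair, pipeline_cfg)
            if truth.touches_border:
                assert m.qc in (QCStatus.BORDER_ATTACHED, QCStatus.NO_OBJECT)
            else:
                assert m.qc is QCStatus.OK

    def test_video_median_recovers_truth_with_contamination(self, default_scene, pipeline_cfg):
        cfg = dataclasses.replace(
            default_scene, border_fraction=0.2, blur_fraction=0.1, depth_noise_sd=5.0
        )
        frames, _ = simulate_video(cfg, 60, seed=21)
        ms = [measure_frame(f, pipeline_cfg) for f in frames]
        length, width, n = aggregate_length_width(ms)
        assert n >= 30
        assert length == pytest.approx(cfg.pig_length, abs=3.0)
        assert width == pytest.approx(cfg.pig_width, abs=3.0)
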