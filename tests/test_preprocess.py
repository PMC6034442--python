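"""Segmentation, curvedness, orientation and metric scaling."""
import math

import numpy as np
import pytest

from cowmon import synthetic as syn
from cowmon.depthio import CameraGeometry, DepthFrame
from cowmon.errors import DegenerateInputError, ValidationError
from cowmon.preprocess import (
    CurvednessMap,
    PreprocessParams,
    curvedness,
    estimate_orientation,
    largest_component,
    match_region,
    metric_grid,
    pixel_pitch,
    rotate_to_major_axis,
    segment_cow,
)


def _flat_scene(shape=(64, 64), floor=2300.0):
    return DepthFrame(np.full(shape, floor))


class TestSegmentCow:
    def test_frame_equal_background_gives_none(self):
        bg = _flat_scene()
        assert segment_cow(DepthFrame(bg.depth.copy()), bg) is None

    def test_every_generated_background_segments_to_none(self, scene_small):
        bg = syn.generate_background(scene_small)
        assert segment_cow(DepthFrame(bg.depth.copy()), bg) is None

    def test_small_blob_below_min_area(self):
        bg = _flat_scene()
        frame = DepthFrame(bg.depth.copy())
        frame.depth[10:30, 10:30] = 1200.0  # 400 px < 500 px minimum
        assert segment_cow(frame, bg) is None

    def test_range_threshold_excludes_legs(self):
        """Body pixels at 1.2 m kept, leg pixels at 1.4 m cut at 1.35 m."""
        bg = _flat_scene((80, 80))
        frame = DepthFrame(bg.depth.copy())
        frame.depth[20:50, 20:50] = 1200.0   # body: 900 px
        frame.depth[50:60, 30:40] = 1400.0   # legs, attached below the body
        seg = segment_cow(frame, bg)
        assert seg is not None
        assert seg.area_px == 900
        assert not seg.mask[50:60, 30:40].any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            segment_cow(_flat_scene((10, 10)), _flat_scene((12, 12)))

    def test_mask_is_single_component_with_filled_heights(
        self, scene_small, background_small
    ):
        cow = syn.CowShapeParams(dropout_rate=0.1, seed=11)
        frame = syn.generate_cow_frame(scene_small, cow, 0.0)
        seg = segment_cow(frame, background_small)
        from scipy import ndimage

        _, n = ndimage.label(seg.mask)
        assert n == 1
        assert np.isfinite(seg.height_map[seg.mask]).all()


class TestLargestComponent:
    def test_smaller_component_removed(self):
        m = np.zeros((50, 50), bool)
        m[5:35, 5:25] = True   # 600 px
        m[40:46, 40:45] = True  # 30 px
        out = largest_component(m)
        assert out.sum() == 600
        assert not out[40:46, 40:45].any()

    def test_single_component_unchanged(self):
        m = np.zeros((20, 20), bool)
        m[3:9, 4:12] = True
        assert np.array_equal(largest_component(m), m)

    def test_all_false_stays_all_false(self):
        assert not largest_component(np.zeros((5, 5), bool)).any()

    def test_equal_size_tie_goes_to_scan_order(self):
        m = np.zeros((10, 10), bool)
        m[1, 1:4] = True  # first in scan order
        m[8, 5:8] = True
        out = largest_component(m)
        assert out[1, 1:4].all()
        assert not out[8].any()


class TestCurvedness:
    def test_inclined_plane_is_zero(self):
        n = 120
        yy, xx = np.mgrid[:n, :n]
        cmap = curvedness(0.31 * xx + 0.17 * yy + 4.0, np.ones((n, n), bool))
        assert cmap.cmax == 0.0
        assert np.all(cmap.values == 0.0)

    def test_sphere_closed_form(self):
        r, n = 120.0, 220
        yy, xx = np.mgrid[:n, :n] - (n - 1) / 2
        rho2 = xx**2 + yy**2
        capm = rho2 < (0.6 * r) ** 2
        h = np.zeros((n, n))
        h[capm] = np.sqrt(r**2 - rho2[capm])
        cmap = curvedness(h, capm, smooth_sigma=5.0)
        interior = rho2 < (0.3 * r) ** 2
        assert np.median(cmap.raw[interior]) == pytest.approx(math.sqrt(2) / r, rel=0.05)
        assert cmap.values.max() == pytest.approx(1.0)
        assert np.all((cmap.values >= 0) & (cmap.values <= 1))

    def test_cylinder_closed_form(self):
        r, n = 80.0, 220
        yy, _ = np.mgrid[:n, :n] - (n - 1) / 2
        m = np.abs(yy) < 0.6 * r
        h = np.where(m, np.sqrt(np.clip(r**2 - yy**2, 0, None)), 0.0)
        cmap = curvedness(h, m, smooth_sigma=5.0)
        mid = np.abs(yy) < 0.3 * r
        assert np.median(cmap.raw[mid]) == pytest.approx(1.0 / r, rel=0.05)

    def test_translation_invariance(self, clean_segment):
        a = curvedness(clean_segment.height_map, clean_segment.mask)
        b = curvedness(clean_segment.height_map + 137.5, clean_segment.mask)
        assert np.allclose(a.raw, b.raw)
        assert np.allclose(a.values, b.values)

    def test_outside_mask_zero(self, clean_segment):
        cmap = curvedness(clean_segment.height_map, clean_segment.mask)
        assert np.all(cmap.values[~clean_segment.mask] == 0.0)


def _ridge_map(angle_deg, n=200, sigma=6.0, amp=30.0):
    yy, xx = np.mgrid[:n, :n] - (n - 1) / 2
    th = math.radians(angle_deg)
    dist = xx * math.sin(th) + yy * math.cos(th)
    h = amp * np.exp(-(dist**2) / (2 * sigma**2))
    return curvedness(h, np.ones((n, n), bool), smooth_sigma=3.0)


class TestOrientation:
    @pytest.mark.parametrize("angle", [0.0, 17.0, 45.0, 90.0, -30.0])
    def test_known_ridge_angle(self, angle):
        est = estimate_orientation(_ridge_map(angle), top_pct=5)
        assert est == pytest.approx(angle, abs=1.0)

    def test_equivariance_mod_180(self):
        base = estimate_orientation(_ridge_map(10.0))
        shifted = estimate_orientation(_ridge_map(10.0 + 25.0))
        assert (shifted - base) % 180 == pytest.approx(25.0, abs=1.5)

    def test_too_few_survivors_raises(self):
        vals = np.zeros((20, 20))
        vals[3, 3] = 1.0
        cmap = CurvednessMap(values=vals, raw=vals, cmax=1.0, mask=vals > 0)
        with pytest.raises(DegenerateInputError):
            estimate_orientation(cmap)


class TestRotation:
    def test_zero_angle_is_identity(self, clean_segment):
        out = rotate_to_major_axis(clean_segment, 0.0)
        assert np.array_equal(out.mask, clean_segment.mask)
        both = clean_segment.mask
        assert np.array_equal(out.height_map[both], clean_segment.height_map[both])

    def test_round_trip_heights(self, clean_segment):
        fwd = rotate_to_major_axis(clean_segment, 17.0)
        back = rotate_to_major_axis(fwd, -17.0)
        both = clean_segment.mask & back.mask
        both &= np.isfinite(back.height_map) & np.isfinite(clean_segment.height_map)
        rms = np.sqrt(np.mean((back.height_map[both] - clean_segment.height_map[both]) ** 2))
        assert rms <= 2.0

    def test_orientation_after_alignment_is_zero(self, clean_segment):
        """Estimate-then-rotate leaves a horizontally aligned ridge."""
        cmap = curvedness(clean_segment.height_map, clean_segment.mask)
        angle = estimate_orientation(cmap)
        rotated = rotate_to_major_axis(clean_segment, angle)
        cmap2 = curvedness(rotated.height_map, rotated.mask)
        assert estimate_orientation(cmap2) == pytest.approx(0.0, abs=1.0)
        assert rotated.orientation_deg == pytest.approx(angle)


class TestMatchRegion:
    def test_exact_copy_scores_one(self):
        rng = np.random.default_rng(0)
        img = rng.random((60, 80))
        tpl = img[10:30, 20:50].copy()
        cmap = CurvednessMap(values=img, raw=img, cmax=1.0, mask=np.ones_like(img, bool))
        rc = match_region(cmap, {"rear": tpl}, ncc_threshold=0.9)
        assert rc.label == "rear"
        assert rc.score == pytest.approx(1.0, abs=1e-6)

    def test_all_zero_curvedness_matches_nothing(self, templates_small):
        z = np.zeros((240, 320))
        cmap = CurvednessMap(values=z, raw=z, cmax=0.0, mask=np.ones_like(z, bool))
        assert match_region(cmap, templates_small, 0.5).label == "none"

    def test_rear_view_labelled_rear(self, scene_small, background_small, templates_small):
        """A cow with only its rear in the field of view matches the rear template."""
        cow = syn.CowShapeParams(seed=5)
        frame = syn.generate_cow_frame(scene_small, cow, position_x=620.0)
        seg = segment_cow(frame, background_small)
        cmap = curvedness(seg.height_map, seg.mask)
        rc = match_region(cmap, templates_small, 0.5)
        assert rc.label == "rear"
        assert rc.score > 0.5

    def test_oversized_template_rejected(self):
        z = np.zeros((20, 20))
        cmap = CurvednessMap(values=z, raw=z, cmax=0.0, mask=np.ones_like(z, bool))
        with pytest.raises(ValidationError):
            match_region(cmap, {"x": np.zeros((30, 30))}, 0.5)


class TestMetric:
    def test_fov_width_at_rig_distance(self):
        g = CameraGeometry()
        w, _ = g.fov_mm(2300.0)
        assert round(w / 1000.0, 1) == 2.5

    def test_zero_depth_excluded(self):
        g = CameraGeometry()
        x, y = metric_grid(np.zeros((4, 4)), g)
        assert np.isnan(x).all() and np.isnan(y).all()

    def test_right_angle_lens(self):
        g = CameraGeometry(theta_horz_deg=90.0)
        depth = np.full((10, 10), 1000.0)
        x, _ = metric_grid(depth, g)
        # full-image extent equals 2 * d * tan(45 deg) = 2000 mm
        dx, _ = pixel_pitch(depth, g)
        assert dx[0, 0] * 10 == pytest.approx(2000.0)
        assert x[0, -1] - x[0, 0] == pytest.approx(2000.0 * 9 / 10)

    def test_extent_matches_fov_at_uniform_depth(self):
        g = CameraGeometry()
        depth = np.full((48, 64), 2300.0)
        dx, dy = pixel_pitch(depth, g)
        w, h = g.fov_mm(2300.0)
        assert dx[0, 0] * 64 == pytest.approx(w)
        assert dy[0, 0] * 48 == pytest.approx(h)
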