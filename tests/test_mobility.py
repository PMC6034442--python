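"""Spine extraction, parabola fitting, motion gating and lameness calls."""
import numpy as np
import pytest

from cowmon import synthetic as syn
from cowmon.errors import DegenerateInputError, SessionUnusableError
from cowmon.mobility import (
    classify_lameness,
    extract_spine_roi,
    fit_spine,
    is_moving,
    normalised_arch,
    session_statistic,
    spine_points,
)
from cowmon.preprocess import curvedness, segment_cow


@pytest.fixture(scope="module")
def ridge_segment(scene_small, background_small):
    cow = syn.CowShapeParams(
        spine_arch_a=-1e-4, bump_sharpness=0.0, noise_sd=0.0, dropout_rate=0.0
    )
    seg = segment_cow(
        syn.generate_cow_frame(scene_small, cow, 0.0), background_small
    )
    cmap = curvedness(seg.height_map, seg.mask)
    return seg, cmap


class TestSpineRoi:
    def test_roi_is_subset_of_mask(self, ridge_segment):
        seg, cmap = ridge_segment
        roi = extract_spine_roi(cmap, seg)
        assert roi.any()
        assert not (roi & ~seg.mask).any()

    def test_roi_centred_on_spine_centreline(self, ridge_segment):
        seg, cmap = ridge_segment
        roi = extract_spine_roi(cmap, seg)
        centroid_row = np.argwhere(seg.mask).mean(axis=0)[0]
        rows = np.argwhere(roi)[:, 0]
        assert abs(np.median(rows) - centroid_row) <= 2.0

    def test_flat_disc_has_no_ridge(self):
        """A featureless flat object yields an empty ROI (frame discarded)."""
        from cowmon.depthio import CameraGeometry
        from cowmon.preprocess import CowSegment

        n = 120
        yy, xx = np.mgrid[:n, :n] - (n - 1) / 2
        mask = xx**2 + yy**2 < 45**2
        seg = CowSegment(
            mask=mask,
            height_map=np.where(mask, 1000.0, np.nan),
            depth=np.full((n, n), 1300.0),
            geometry=CameraGeometry(),
        )
        cmap = curvedness(seg.height_map, seg.mask)
        roi = extract_spine_roi(cmap, seg)
        assert not roi.any()


class TestSpinePoints:
    def test_constant_ridge_heights(self, scene_small, background_small):
        cow = syn.CowShapeParams(
            spine_arch_a=0.0, spine_skew_b=0.0, bump_sharpness=0.0,
            noise_sd=0.0, dropout_rate=0.0,
        )
        seg = segment_cow(
            syn.generate_cow_frame(scene_small, cow, 0.0), background_small
        )
        cmap = curvedness(seg.height_map, seg.mask)
        roi = extract_spine_roi(cmap, seg)
        x, h = spine_points(roi, seg)
        # flat spine: centreline at body_height + prominence everywhere
        assert np.ptp(h) < 2.0
        assert np.all(np.diff(x) > 0)

    def test_column_tie_takes_smaller_row(self):
        from cowmon.depthio import CameraGeometry
        from cowmon.preprocess import CowSegment

        h = np.full((10, 6), 500.0)
        h[3, 2] = h[7, 2] = 800.0  # two equal maxima in column 2
        mask = np.ones((10, 6), bool)
        seg = CowSegment(
            mask=mask, height_map=h, depth=np.full((10, 6), 1500.0),
            geometry=CameraGeometry(),
        )
        roi = np.zeros((10, 6), bool)
        roi[:, 2] = True
        x, hh = spine_points(roi, seg, smooth_sigma=0.0)
        assert hh[0] == 800.0
        assert seg.x_mm[3, 2] == x[0]

    def test_points_lie_on_generating_parabola(self, ridge_segment):
        seg, cmap = ridge_segment
        roi = extract_spine_roi(cmap, seg)
        x, h = spine_points(roi, seg)
        pred = 1330.0 - 1e-4 * x**2
        assert np.median(np.abs(h - pred)) < 3.0


class TestFitSpine:
    def test_exact_parabola_recovered_to_machine_precision(self):
        x = np.linspace(-400, 400, 41)
        h = -1e-5 * x**2 + 900.0
        c = fit_spine(x, h, x_center=0.0)
        assert c.a == pytest.approx(-1e-5, rel=1e-9)
        assert c.b == pytest.approx(0.0, abs=1e-12)
        assert c.c == pytest.approx(900.0)
        assert c.rms_residual < 1e-9

    def test_flat_spine(self):
        x = np.linspace(-300, 300, 25)
        c = fit_spine(x, np.full_like(x, 950.0))
        assert c.a == pytest.approx(0.0, abs=1e-15)
        assert c.b == pytest.approx(0.0, abs=1e-12)
        assert c.c == pytest.approx(950.0)

    def test_quadratic_coefficient_translation_invariant(self):
        rng = np.random.default_rng(1)
        x = np.linspace(-400, 400, 60)
        h = -3e-5 * x**2 + 2e-3 * x + 1200 + rng.normal(0, 1, x.size)
        a0 = fit_spine(x, h).a
        a1 = fit_spine(x + 5000.0, h).a
        assert a1 == pytest.approx(a0, rel=1e-9)

    def test_too_few_distinct_x_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_spine([1.0, 1.0, 1.0, 2.0], [3.0, 3.1, 3.2, 4.0])


class TestMotionGate:
    def _segments(self, scene, background, n, step):
        cow = syn.CowShapeParams(
            body_length=700, body_width=450, body_height=1200,
            spine_arch_a=1e-4, noise_sd=0.0, dropout_rate=0.0,
        )
        frames = syn.generate_walk_sequence(scene, cow, n, step, start_x=-step * (n - 1) / 2)
        return [segment_cow(f, background) for f in frames]

    def test_stationary_sequence_not_moving(self, scene_small, background_small):
        segs = self._segments(scene_small, background_small, 4, 0.0)
        assert is_moving(segs) is False

    def test_walking_sequence_moving(self, scene_small, background_small):
        segs = self._segments(scene_small, background_small, 4, 40.0)
        assert is_moving(segs) is True

    def test_jitter_below_threshold_not_moving(self):
        class Stub:
            def __init__(self, x):
                self.centroid_x_mm = x

        xs = [0.0, 3.0, 0.0, -3.0, 0.0, 3.0]
        assert is_moving([Stub(x) for x in xs], min_step_mm=10.0) is False


class TestSessionStatistic:
    def test_all_flat_gives_zero(self):
        assert session_statistic([0.0, 0.0, 0.0]) == 0.0

    def test_minimum_over_frames(self):
        assert session_statistic([-0.1, -0.5, -0.2]) == -0.5

    def test_empty_session_unusable(self):
        with pytest.raises(SessionUnusableError):
            session_statistic([])

    def test_arched_cow_scores_above_dipped_cow(
        self, scene_small, background_small
    ):
        """An arched (lame-posture) spine yields a larger session statistic
        than a sound, dipped topline."""
        stats = {}
        for name, a in (("arched", -2.5e-4), ("dipped", 7e-4)):
            cow = syn.CowShapeParams(
                spine_arch_a=a, bump_sharpness=0.0, noise_sd=0.0, dropout_rate=0.0
            )
            seg = segment_cow(
                syn.generate_cow_frame(scene_small, cow, 0.0), background_small
            )
            cmap = curvedness(seg.height_map, seg.mask)
            roi = extract_spine_roi(cmap, seg)
            x, h = spine_points(roi, seg)
            curve = fit_spine(x, h, x_center=seg.centroid_x_mm)
            stats[name] = normalised_arch(
                curve, seg.major_axis_length_mm(), float(np.mean(h))
            )
        assert stats["arched"] > stats["dipped"] + 0.3

    def test_arch_statistic_monotone_in_spine_arch(
        self, scene_small, background_small
    ):
        values = []
        for a in (-5e-5, -1e-4, -2e-4, -4e-4):
            cow = syn.CowShapeParams(
                spine_arch_a=a, bump_sharpness=0.0, noise_sd=0.0, dropout_rate=0.0
            )
            seg = segment_cow(
                syn.generate_cow_frame(scene_small, cow, 0.0), background_small
            )
            cmap = curvedness(seg.height_map, seg.mask)
            roi = extract_spine_roi(cmap, seg)
            x, h = spine_points(roi, seg)
            curve = fit_spine(x, h, x_center=seg.centroid_x_mm)
            values.append(
                normalised_arch(curve, seg.major_axis_length_mm(), float(np.mean(h)))
            )
        assert values == sorted(values)


class TestClassify:
    @pytest.mark.parametrize(
        "stat,expected",
        [(-0.2, True), (-0.5, False), (-0.3, True), (0.4, True), (-10.0, False)],
    )
    def test_threshold_rule(self, stat, expected):
        assert classify_lameness(stat) is expected

    def test_nonfinite_rejected(self):
        with pytest.raises(DegenerateInputError):
            classify_lameness(float("nan"))
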