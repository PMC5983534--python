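import numpy as np
import pytest

from gazeclean import (
    NoiseConfig,
    calibration_plan,
    gen_layout,
    long_session,
    ng_plan,
    simulate_session,
)
from gazeclean.errors import EmptyInputError, InvalidArgumentError, LayoutOverflowError
from gazeclean.metrics import closeness
from gazeclean.gaze_io import FixationChunk


class TestLayouts:
    def test_ng_is_an_arithmetic_row(self):
        layout = gen_layout("ng", spacing=50)
        xs = [e.x for e in layout.entities]
        assert len(xs) == 9
        assert np.allclose(np.diff(xs), 50.0)
        assert len({e.y for e in layout.entities}) == 1

    @pytest.mark.parametrize("spacing,font", [(100, 50), (70, 35), (50, 25)])
    def test_ng_spacing_to_font_ratio_is_two(self, spacing, font):
        layout = gen_layout("ng", spacing=spacing)
        assert layout.entities[0].height == font

    def test_rr_two_columns(self):
        layout = gen_layout("rr", words_per_column=16)
        assert len(layout.entities) == 32
        assert len({e.x for e in layout.entities}) == 2

    def test_calibration_nine_points_center_at_screen_center(self, geom):
        layout = gen_layout("calibration", geom=geom)
        assert len(layout.entities) == 9
        center = layout.entity("S5")
        assert (center.x, center.y) == (geom.width_px / 2, geom.height_px / 2)

    def test_overflowing_spacing_rejected(self):
        with pytest.raises(LayoutOverflowError):
            gen_layout("ng", spacing=200)

    def test_nonstandard_spacing_warns(self):
        with pytest.warns(UserWarning):
            gen_layout("ng", spacing=60)

    def test_rectangle_aois_do_not_overlap(self):
        for task, kw in [("ng", dict(spacing=50)), ("rr", dict(words_per_column=16))]:
            layout = gen_layout(task, **kw)
            aois = [layout.aoi(e.id, "rectangle") for e in layout.entities]
            for i, a in enumerate(aois):
                for b in aois[i + 1 :]:
                    dx = abs(a.center[0] - b.center[0])
                    dy = abs(a.center[1] - b.center[1])
                    assert (
                        dx > a.half_extents[0] + b.half_extents[0]
                        or dy > a.half_extents[1] + b.half_extents[1]
                    )


class TestSimulateSession:
    def test_noise_free_identity_session_sits_on_targets(self, ng50, noise_free):
        session = simulate_session(ng50, ng_plan(ng50, [1, 3, 5, 7]), noise_free)
        assert np.allclose(session.trace.xy, session.clean_xy)
        for tid, t0, t1 in session.dwell_windows():
            mask = (session.trace.t >= t0) & (session.trace.t <= t1)
            centroid = session.trace.xy[mask].mean(axis=0)
            assert np.allclose(centroid, ng50.entity(tid).position, atol=1e-9)

    def test_calibration_plan_dwell_counts(self, calibration_layout, noise_free):
        session = simulate_session(
            calibration_layout, calibration_plan(calibration_layout), noise_free,
            transition="pursuit",
        )
        windows = session.dwell_windows()
        assert len(windows) == 9
        assert int(session.dwell_mask.sum()) >= 9 * 150
        # pursuit transitions exist and are excluded from dwells
        assert (~session.dwell_mask).sum() > 0

    def test_same_seed_bit_identical(self, ng50):
        noise = NoiseConfig(sigma=8, distortion=[[1.05, 0.02], [0, 0.97]], seed=7)
        a = simulate_session(ng50, ng_plan(ng50, [1, 2, 3]), noise, seed=7)
        b = simulate_session(ng50, ng_plan(ng50, [1, 2, 3]), noise, seed=7)
        assert np.array_equal(a.trace.xy, b.trace.xy)
        assert a.clicks == b.clicks

    def test_distortion_applied_as_right_multiplication(self, ng50):
        D = np.array([[1.1, 0.0], [0.05, 0.9]])
        noise = NoiseConfig(sigma=0.0, outlier_prob=0.0, distortion=D, seed=0)
        session = simulate_session(ng50, ng_plan(ng50, [5]), noise)
        assert np.allclose(session.trace.xy, session.clean_xy @ D)

    def test_clicks_emitted_at_dwell_ends_with_ids(self, ng50, noise_free):
        session = simulate_session(ng50, ng_plan(ng50, [2, 4, 6, 8]), noise_free)
        assert [c.target_id for c in session.clicks] == [2, 4, 6, 8]
        for c in session.clicks:
            assert c.t <= session.trace.t[-1]

    def test_calibration_session_emits_no_clicks(self, calibration_layout, noise_free):
        session = simulate_session(
            calibration_layout, calibration_plan(calibration_layout, 1.0), noise_free
        )
        assert session.clicks == []

    def test_empty_plan_rejected(self, ng50, noise_free):
        with pytest.raises(EmptyInputError):
            simulate_session(ng50, [], noise_free)

    def test_unknown_target_rejected(self, ng50, noise_free):
        with pytest.raises(InvalidArgumentError):
            simulate_session(ng50, [(42, 1.0)], noise_free)

    def test_invalid_noise_config(self):
        with pytest.raises(InvalidArgumentError):
            NoiseConfig(sigma=-1)
        with pytest.raises(InvalidArgumentError):
            NoiseConfig(distortion=np.zeros((2, 2)))


class TestLongSession:
    def _per_minute_raw_cl(self, session):
        out = {}
        for tid, t0, t1 in session.dwell_windows():
            mask = (session.trace.t >= t0) & (session.trace.t <= t1)
            pts = session.trace.xy[mask]
            cl = closeness(FixationChunk(pts, 0, len(pts) - 1))
            out.setdefault(int(t0 // 60), []).append((cl, len(pts)))
        return {
            m: sum(c * n for c, n in v) / sum(n for _, n in v) for m, v in sorted(out.items())
        }

    def test_duration_sample_count(self, ng50):
        noise = NoiseConfig(sigma=8, outlier_prob=0.0, seed=0)
        session = long_session(ng50, 900, noise, fatigue_ramp=0.0, seed=0)
        # 15 min of dwells plus saccade ramps: within ~5% of 27000 samples
        assert abs(len(session.trace) - 27000) < 1500

    def test_zero_ramp_keeps_raw_closeness_stationary(self, ng50):
        noise = NoiseConfig(sigma=8, outlier_prob=0.0, seed=1)
        session = long_session(ng50, 900, noise, fatigue_ramp=0.0, seed=1)
        cl = list(self._per_minute_raw_cl(session).values())[:15]
        assert (max(cl) - min(cl)) / np.mean(cl) < 0.5  # no trend beyond sampling noise
        assert abs(cl[-1] - cl[0]) / cl[0] < 0.3

    def test_positive_ramp_makes_raw_closeness_increase(self, ng50):
        noise = NoiseConfig(sigma=8, outlier_prob=0.0, seed=2)
        session = long_session(ng50, 900, noise, fatigue_ramp=2.0, seed=2)
        cl = list(self._per_minute_raw_cl(session).values())[:15]
        assert all(b > a for a, b in zip(cl, cl[1:]))
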