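import numpy as np
import numpy.testing as npt
import pytest

from uterodyn.events import (
    ContractionEvent,
    DetectionParams,
    contraction_rate,
    detect_events,
    event_features,
    events_to_frame,
    halfmax_duration,
    local_baseline,
)
from uterodyn.timecourse import smooth


def tukey_dip(t, onset, duration, amplitude, taper=0.25, baseline=100.0):
    x = (t - onset) / duration
    p = np.ones_like(x)
    p = np.where(x < taper, 0.5 * (1 - np.cos(np.pi * np.clip(x, 0, 1) / taper)), p)
    p = np.where(
        x > 1 - taper, 0.5 * (1 - np.cos(np.pi * np.clip(1 - x, 0, 1) / taper)), p
    )
    p = np.where((x < 0) | (x > 1), 0.0, p)
    return baseline * (1 - amplitude * p)


class TestDetect:
    def test_constant_series_no_events(self):
        t = np.arange(60) * 15.0
        assert detect_events(np.full(60, 100.0), t) == []

    def test_single_frame_dip_ignored(self):
        t = np.arange(30) * 15.0
        v = np.full(30, 100.0)
        v[15] = 80.0
        assert detect_events(v, t, DetectionParams(min_consecutive=2)) == []

    def test_synthetic_dip_detected_with_anchors(self):
        t = np.arange(80) * 15.0
        v = smooth(tukey_dip(t, 400.0, 300.0, 0.2), 5)
        events = detect_events(v, t)
        assert len(events) == 1
        ev = events[0]
        assert not ev.truncated
        assert t[ev.pre_rest_index] < 400.0
        assert t[ev.post_rest_index] > 700.0

    def test_merge_gap(self):
        t = np.arange(80) * 15.0
        v = smooth(
            tukey_dip(t, 300.0, 150.0, 0.2) + tukey_dip(t, 480.0, 150.0, 0.2) - 100.0,
            5,
        )
        merged = detect_events(v, t, DetectionParams(merge_gap_frames=4))
        split = detect_events(v, t, DetectionParams(merge_gap_frames=0))
        assert len(merged) <= len(split)

    def test_truncated_at_scan_edges(self):
        t = np.arange(60) * 15.0
        v = smooth(tukey_dip(t, -100.0, 300.0, 0.2), 5)
        events = detect_events(v, t)
        assert events and events[0].truncated_start

    def test_no_rest_whole_session_truncated(self):
        t = np.array([0.0, 15.0, 30.0])
        v = np.array([100.0, 70.0, 40.0])  # no frame near the reference
        with pytest.warns(UserWarning, match="no rest"):
            events = detect_events(v, t)
        assert len(events) == 1
        assert events[0].truncated_start and events[0].truncated_end
        assert (events[0].start_index, events[0].end_index) == (0, 2)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            detect_events(np.array([1.0, 2.0]), np.array([0.0, 15.0]))


class TestLocalBaseline:
    def _event(self, **kw):
        base = dict(start_index=2, end_index=6, pre_rest_index=1, post_rest_index=7)
        base.update(kw)
        return ContractionEvent(**base)

    def test_linear_midpoint_example(self):
        # pre-rest 100 at t=0, post-rest 90 at t=200 -> 95 at t=100
        t = np.array([0.0, 0.0, 25, 50, 100, 150, 175, 200, 220])
        x = np.array([100.0, 100, 70, 60, 55, 60, 70, 90, 90])
        ev = self._event(pre_rest_index=0, start_index=1, end_index=7,
                         post_rest_index=7)
        baseline = local_baseline(ev, x, t)
        mid = np.interp(100.0, t[ev.window()[0] : ev.window()[1] + 1], baseline)
        assert mid == pytest.approx(95.0)

    def test_truncated_end_constant(self):
        t = np.arange(9) * 10.0
        x = np.array([100.0, 100, 70, 60, 55, 50, 45, 40, 35])
        ev = self._event(post_rest_index=None, truncated_end=True, end_index=8)
        baseline = local_baseline(ev, x, t)
        npt.assert_allclose(baseline, 100.0)

    def test_both_truncated_uses_global_rest(self):
        t = np.arange(9) * 10.0
        x = np.linspace(90, 40, 9)
        ev = self._event(
            pre_rest_index=None, post_rest_index=None,
            truncated_start=True, truncated_end=True,
            start_index=0, end_index=8,
        )
        baseline = local_baseline(ev, x, t, global_rest_index=0)
        npt.assert_allclose(baseline, 90.0)


class TestHalfmax:
    def test_symmetric_triangle(self):
        # triangular dip with a 240 s base -> half-max width 120 s = 2 min
        t = np.arange(25) * 20.0
        v = np.full(25, 100.0)
        for i, ti in enumerate(t):
            if 120 <= ti <= 360:
                v[i] = 100.0 - 20.0 * (1 - abs(ti - 240.0) / 120.0)
        ev = ContractionEvent(start_index=6, end_index=18, pre_rest_index=5,
                              post_rest_index=19)
        minutes, lower = halfmax_duration(ev, v, t)
        assert not lower
        assert minutes == pytest.approx(2.0)

    def test_time_rescaling_scales_duration(self):
        t = np.arange(40) * 15.0
        v = tukey_dip(t, 150.0, 240.0, 0.2)
        ev = detect_events(smooth(v, 5), t)[0]
        d1, _ = halfmax_duration(ev, smooth(v, 5), t)
        for factor in (2.0, 3.0):
            d2, _ = halfmax_duration(ev, smooth(v, 5), t * factor)
            assert d2 == pytest.approx(factor * d1, rel=1e-9)

    def test_truncated_event_lower_bound(self):
        t = np.arange(30) * 15.0
        v = smooth(tukey_dip(t, 300.0, 400.0, 0.25), 5)  # runs past scan end
        events = detect_events(v, t)
        assert events and events[0].truncated_end
        minutes, lower = halfmax_duration(events[0], v, t)
        assert lower
        assert minutes > 0

    def test_flat_event_rejected(self):
        t = np.arange(10) * 10.0
        v = np.full(10, 50.0)
        ev = ContractionEvent(start_index=3, end_index=6, pre_rest_index=2,
                              post_rest_index=7)
        with pytest.raises(ValueError, match="deviation"):
            halfmax_duration(ev, v, t)


class TestEventFeatures:
    def _session(self, trend_per_s=0.0):
        t = np.arange(90) * 15.0
        v = tukey_dip(t, 400.0, 300.0, 0.2) + trend_per_s * t
        series = {
            "v_placenta": smooth(v, 5),
            "a_wall": smooth(np.full(90, 500.0) + 0.05 * (100 - tukey_dip(t, 400, 300, 0.2)) * 10, 5),
            "sphericity": smooth(0.7 + 0.0001 * (100 - tukey_dip(t, 400, 300, 0.2)), 5),
            "dr2s": smooth(0.0002 * (100 - tukey_dip(t, 400, 300, 0.2)), 5),
        }
        return t, series

    def test_feature_signs_and_magnitudes(self):
        t, series = self._session()
        ev = detect_events(series["v_placenta"], t)[0]
        event_features(ev, series, t)
        assert ev.max_volume_drop_pct == pytest.approx(20.0, abs=0.5)
        assert ev.max_wall_area_change_pct > 0
        assert ev.max_sphericity_change == pytest.approx(0.002, abs=3e-4)
        assert ev.dr2s_change_per_ms == pytest.approx(0.004, abs=6e-4)
        assert ev.halfmax_duration_min == pytest.approx(225.0 / 60.0, abs=0.25)

    def test_drop_invariant_to_linear_trend(self):
        # the interpolated local baseline absorbs the trend; the small
        # residual is only the % scale change from the trending baseline
        _, series0 = self._session(0.0)
        t, series1 = self._session(trend_per_s=0.002)
        ev0 = detect_events(series0["v_placenta"], t)[0]
        ev1 = detect_events(series1["v_placenta"], t)[0]
        event_features(ev0, series0, t)
        event_features(ev1, series1, t)
        assert not ev0.truncated and not ev1.truncated
        assert ev1.max_volume_drop_pct == pytest.approx(
            ev0.max_volume_drop_pct, abs=0.5
        )
        # a naive global-rest baseline would be off by the full trend excursion
        naive = 100.0 * (1 - series1["v_placenta"].min() / series1["v_placenta"][0])
        assert abs(naive - ev0.max_volume_drop_pct) > abs(
            ev1.max_volume_drop_pct - ev0.max_volume_drop_pct
        )

    def test_zero_amplitude_pseudo_event(self):
        t = np.arange(20) * 15.0
        flat = np.full(20, 100.0)
        series = {
            "v_placenta": flat,
            "a_wall": np.full(20, 500.0),
            "sphericity": np.full(20, 0.7),
            "dr2s": np.zeros(20),
        }
        ev = ContractionEvent(start_index=8, end_index=12, pre_rest_index=7,
                              post_rest_index=13)
        event_features(ev, series, t)
        assert ev.max_volume_drop_pct == 0.0
        assert ev.max_wall_area_change_pct == 0.0
        assert ev.max_sphericity_change == 0.0
        assert ev.dr2s_change_per_ms == 0.0
        assert ev.halfmax_duration_min is None  # no deviation to time

    def test_dr2s_extremum_mode(self):
        t, series = self._session()
        ev = detect_events(series["v_placenta"], t)[0]
        event_features(ev, series, t, dr2s_mode="extremum")
        assert ev.dr2s_change_per_ms >= 0.004 - 6e-4
        with pytest.raises(ValueError):
            event_features(ev, series, t, dr2s_mode="bogus")


class TestContractionRate:
    def test_examples(self):
        assert contraction_rate(3, 1800.0) == pytest.approx(6.0)
        assert contraction_rate(0, 1800.0) == 0.0
        assert contraction_rate(2, 32 * 60.0) == pytest.approx(3.75)

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            contraction_rate(1, 0.0)


class TestEventsToFrame:
    def test_columns(self):
        ev = ContractionEvent(start_index=1, end_index=3)
        df = events_to_frame([ev], np.arange(5) * 10.0)
        assert df.loc[0, "start_s"] == 10.0
        assert "max_volume_drop_pct" in df.columns
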