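"""Extrema detection, per-transition ratios, artifact filters, windowing."""

import numpy as np
import pytest

from cpfr import (
    BeatSeries,
    Extremum,
    TransitionMetrics,
    build_transitions,
    detect_extrema,
    flag_initial_unstable,
    flag_outliers,
    window_average,
)
from cpfr.pipeline import process_recording
from cpfr.signal_io import summaries_to_frame
from cpfr.transition_metrics import (
    BeatGapError,
    NoOscillationError,
    _zscore_outlier_mask,
)


def series(t, v):
    return BeatSeries(np.asarray(t, float), np.asarray(v, float))


class TestDetectExtrema:
    def test_sine_extrema_at_quarter_cycles(self):
        t = np.arange(0.0, 300.0, 1.0)
        s = series(t, 90 + 20 * np.sin(2 * np.pi * 0.05 * t))
        ext = detect_extrema(s, 0.05)
        kinds = [e.kind for e in ext]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))
        for e in ext:
            # true extrema at odd multiples of 5 s, +/- one beat
            assert abs((e.time_s - 5.0) % 10.0) <= 1.0 or \
                   abs((e.time_s - 5.0) % 10.0) >= 9.0
            expected = 110.0 if e.kind == "max" else 70.0
            assert e.value == pytest.approx(expected, abs=0.5)

    def test_constant_series_has_no_oscillation(self):
        t = np.arange(0.0, 100.0, 1.0)
        with pytest.raises(NoOscillationError):
            detect_extrema(series(t, np.full_like(t, 90.0)), 0.05)

    def test_asymmetric_sawtooth_spacings(self):
        # rise 9 s / fall 11 s at 0.05 Hz: min->max 9 s, max->min 11 s
        corners_t = [0.0]
        corners_v = [70.0]
        for k in range(15):
            corners_t += [20.0 * k + 9.0, 20.0 * (k + 1)]
            corners_v += [110.0, 70.0]
        t = np.arange(0.0, 300.0, 0.5)
        s = series(t, np.interp(t, corners_t, corners_v))
        ext = detect_extrema(s, 0.05)
        spans = {"rise": [], "fall": []}
        for a, b in zip(ext, ext[1:]):
            spans["rise" if b.kind == "max" else "fall"].append(b.time_s - a.time_s)
        assert np.mean(spans["rise"]) == pytest.approx(9.0, abs=0.6)
        assert np.mean(spans["fall"]) == pytest.approx(11.0, abs=0.6)

    def test_gap_longer_than_half_cycle_is_error(self):
        t = np.arange(0.0, 200.0, 1.0)
        v = 90 + 20 * np.sin(2 * np.pi * 0.05 * t)
        keep = (t < 80) | (t > 95)
        with pytest.raises(BeatGapError, match="gap"):
            detect_extrema(series(t[keep], v[keep]), 0.05)

    def test_alternation_and_spacing_invariants(self, noiseless_recording):
        rec, _ = noiseless_recording(0.10)
        ext = detect_extrema(rec.map_series, 0.10)
        hc = 5.0
        for a, b in zip(ext, ext[1:]):
            assert a.kind != b.kind
            assert 0.5 * hc <= b.time_s - a.time_s <= 1.5 * hc


class TestBuildTransitions:
    def test_inc_hand_arithmetic(self):
        map_ext = [Extremum("min", 0.0, 80.0), Extremum("max", 4.0, 120.0)]
        mcav_ext = [Extremum("min", 0.25, 55.0), Extremum("max", 3.75, 75.0)]
        (tr,) = build_transitions(map_ext, mcav_ext, 0.05)
        assert tr.direction == "INC"
        assert tr.rate_map == pytest.approx(10.0)
        assert tr.rate_mcav == pytest.approx(20.0 / 3.5)
        assert tr.ratio_abs == pytest.approx(0.5714285714, rel=1e-9)
        assert tr.rel_change_map == pytest.approx(0.5)
        assert tr.rel_change_mcav == pytest.approx(20.0 / 55.0)
        assert tr.ratio_rel == pytest.approx((20 / 55 / 3.5) / (0.5 / 4.0), rel=1e-9)
        assert tr.ratio_rel == pytest.approx(0.83116883, rel=1e-6)

    def test_identical_signals_give_unit_ratios(self):
        ext = [Extremum("min", 0.0, 80.0), Extremum("max", 4.5, 120.0),
               Extremum("min", 10.0, 80.0), Extremum("max", 14.5, 120.0)]
        for tr in build_transitions(ext, ext, 0.05):
            assert tr.ratio_abs == pytest.approx(1.0)
            assert tr.ratio_rel == pytest.approx(1.0)

    def test_dec_ratio_positive_after_abs_summary(self):
        map_ext = [Extremum("max", 0.0, 120.0), Extremum("min", 4.0, 80.0)]
        mcav_ext = [Extremum("max", 0.2, 75.0), Extremum("min", 4.2, 55.0)]
        (tr,) = build_transitions(map_ext, mcav_ext, 0.05)
        assert tr.direction == "DEC"
        # equal times: ratio is the delta ratio 20/40
        assert tr.ratio_abs == pytest.approx(0.5)
        assert tr.delta_map == pytest.approx(-40.0)
        (summ,) = [s for s in window_average(
            [tr], [300.0], participant_id="p", frequency_hz=0.05)
            if s.direction == "DEC"]
        assert summ.mean_ratio_abs == pytest.approx(0.5)
        assert summ.mean_delta_map == pytest.approx(40.0)

    def test_unmatched_mcav_marks_incomplete(self):
        map_ext = [Extremum("min", 0.0, 80.0), Extremum("max", 9.0, 120.0),
                   Extremum("min", 20.0, 80.0)]
        mcav_ext = [Extremum("min", 0.3, 55.0), Extremum("max", 9.3, 75.0)]
        trs = build_transitions(map_ext, mcav_ext, 0.05)
        assert [t.exclusion_reason for t in trs] == ["none", "incomplete"]
        assert not trs[1].included

    def test_empty_input_is_empty_output(self):
        assert build_transitions([], [], 0.05) == []


def _toy_transition(i, direction, ratio, t_end):
    sign = 1 if direction == "INC" else -1
    a = Extremum("min" if direction == "INC" else "max", t_end - 5.0,
                 80.0 if direction == "INC" else 120.0)
    b = Extremum("max" if direction == "INC" else "min", t_end,
                 120.0 if direction == "INC" else 80.0)
    return TransitionMetrics(
        index=i, direction=direction, map_from=a, map_to=b,
        mcav_from=None, mcav_to=None,
        delta_map=sign * 40.0, delta_mcav=sign * 40.0 * ratio,
        dt_map=5.0, dt_mcav=5.0,
        rate_map=sign * 8.0, rate_mcav=sign * 8.0 * ratio,
        rel_change_map=sign * 0.5, rel_change_mcav=sign * 0.5 * ratio,
        ratio_abs=ratio, ratio_rel=ratio,
    )


class TestFilters:
    def test_homogeneous_deltas_not_flagged_unstable(self):
        trs = [_toy_transition(i, "INC", 1.0, 10.0 * (i + 1)) for i in range(5)]
        out = flag_initial_unstable(trs)
        assert all(t.included for t in out)

    def test_small_leading_delta_flagged(self):
        trs = [_toy_transition(i, "INC", 1.0, 10.0 * (i + 1)) for i in range(5)]
        small = trs[0]
        trs[0] = TransitionMetrics(**{**small.__dict__, "delta_map": 10.0})
        out = flag_initial_unstable(trs)
        assert not out[0].included
        assert out[0].exclusion_reason == "initial_unstable"
        assert all(t.included for t in out[1:])

    def test_mid_recording_small_delta_untouched_by_leading_rule(self):
        trs = [_toy_transition(i, "INC", 1.0, 10.0 * (i + 1)) for i in range(5)]
        mid = trs[2]
        trs[2] = TransitionMetrics(**{**mid.__dict__, "delta_map": 10.0})
        out = flag_initial_unstable(trs)
        assert all(t.included for t in out)

    def test_three_sd_outlier_hand_arithmetic(self):
        ratios = [1.0] * 14 + [3.0]
        trs = [_toy_transition(i, "INC", r, 10.0 * (i + 1))
               for i, r in enumerate(ratios)]
        out = flag_outliers(trs)
        flagged = [t for t in out if not t.included]
        assert len(flagged) == 1
        assert flagged[0].ratio_abs == 3.0
        assert flagged[0].exclusion_reason == "outlier"
        # z of the outlier: (3 - 1.13333) / 0.516398 = 3.615 > 3
        vals = np.array(ratios)
        z = (3.0 - vals.mean()) / vals.std(ddof=1)
        assert z == pytest.approx(3.615, abs=0.01)

    def test_identical_ratios_never_flagged(self):
        trs = [_toy_transition(i, "DEC", 1.0, 10.0 * (i + 1)) for i in range(8)]
        assert all(t.included for t in flag_outliers(trs))

    def test_small_group_skipped_with_warning(self, caplog):
        trs = [_toy_transition(i, "INC", r, 10.0 * (i + 1))
               for i, r in enumerate([1.0, 50.0])]
        out = flag_outliers(trs)
        assert all(t.included for t in out)

    def test_normal_flag_rate_below_two_percent(self):
        rng = np.random.default_rng(42)
        flags = sum(
            _zscore_outlier_mask(rng.normal(1.0, 0.1, 15), 3.0).sum()
            for _ in range(2000)
        )
        assert flags / (2000 * 15) < 0.02


class TestWindowAverage:
    @pytest.mark.parametrize("freq,counts", [
        (0.05, [3, 6, 9, 12, 15]),
        (0.10, [6, 12, 18, 24, 30]),
    ])
    def test_clean_recording_counts_match_protocol(
            self, noiseless_recording, default_config, freq, counts):
        rec, _ = noiseless_recording(freq)
        default_config.protocol.frequency_hz = freq
        _, summaries = process_recording(rec, default_config)
        df = summaries_to_frame(summaries)
        for direction in ("INC", "DEC"):
            got = df[df.direction == direction].sort_values("window_s")
            assert got["n_included"].tolist() == counts

    def test_all_excluded_gives_empty_summaries(self):
        trs = [_toy_transition(i, "INC", 1.0, 10.0 * (i + 1)) for i in range(3)]
        trs = [TransitionMetrics(**{**t.__dict__, "included": False,
                                    "exclusion_reason": "outlier"}) for t in trs]
        out = window_average(trs, [60, 120, 180, 240, 300],
                             participant_id="p", frequency_hz=0.05)
        assert len(out) == 10
        assert all(s.n_included == 0 for s in out)
        assert all(np.isnan(s.mean_ratio_abs) for s in out)

    def test_prefix_property_under_truncation(
            self, noiseless_recording, default_config):
        rec, _ = noiseless_recording(0.05)
        _, full = process_recording(rec, default_config)
        from dataclasses import replace as drep

        from cpfr.signal_io import Recording
        cut = Recording(
            participant_id=rec.participant_id, frequency_hz=0.05,
            map_series=rec.map_series.truncated(60.0),
            mcav_series=rec.mcav_series.truncated(60.0))
        cfg = default_config
        cfg.protocol.window_lengths_s = (60.0,)
        cfg.reliability.reference_window_s = 60.0
        _, short = process_recording(cut, cfg)
        full60 = {(s.direction): s for s in full if s.window_s == 60.0}
        for s in short:
            assert s.n_included == full60[s.direction].n_included
            assert s.mean_ratio_abs == pytest.approx(
                full60[s.direction].mean_ratio_abs, rel=1e-12)


class TestInvariances:
    def test_mcav_scale_equivariance(self, noiseless_recording):
        rec, _ = noiseless_recording(0.05, gain_inc=0.9, gain_dec=1.1)
        c = 2.0
        map_ext = detect_extrema(rec.map_series, 0.05)
        mcav_ext = detect_extrema(rec.mcav_series, 0.05)
        scaled = BeatSeries(rec.mcav_series.times_s, c * rec.mcav_series.values)
        scaled_ext = detect_extrema(scaled, 0.05)
        base = build_transitions(map_ext, mcav_ext, 0.05)
        mult = build_transitions(map_ext, scaled_ext, 0.05)
        for a, b in zip(base, mult):
            assert b.ratio_abs == pytest.approx(c * a.ratio_abs, rel=1e-12)
            assert b.ratio_rel == pytest.approx(a.ratio_rel, rel=1e-12)

    def test_time_translation_invariance(self, noiseless_recording):
        rec, _ = noiseless_recording(0.05)
        shift = 7.3

        def metrics(map_s, mcav_s):
            return build_transitions(
                detect_extrema(map_s, 0.05), detect_extrema(mcav_s, 0.05), 0.05)

        base = metrics(rec.map_series, rec.mcav_series)
        moved = metrics(
            BeatSeries(rec.map_series.times_s + shift, rec.map_series.values),
            BeatSeries(rec.mcav_series.times_s + shift, rec.mcav_series.values))
        for a, b in zip(base, moved):
            assert b.ratio_abs == pytest.approx(a.ratio_abs, rel=1e-12)
            assert b.dt_map == pytest.approx(a.dt_map, rel=1e-12)
            assert b.map_to.time_s == pytest.approx(a.map_to.time_s + shift)
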