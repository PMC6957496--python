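"""S-peak detector: threshold oracle, refractory rule, scoring, baseline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import equibeat as eb
from equibeat.detect import DetectorConfig, _scan_maxima
from equibeat.synthetic import tall_t_equine_template
from tests.conftest import filtered_lead

RATE = 500.0


class TestAdaptiveThreshold:
    def test_full_history_of_ones(self):
        assert eb.adaptive_threshold(np.ones(200)) == pytest.approx(1.25)

    def test_zero_history(self):
        assert eb.adaptive_threshold(np.zeros(200)) == 0.0

    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(123)
        vals = rng.exponential(size=200)
        brute = (1.25 / 200.0) * sum(float(v) for v in vals)
        assert eb.adaptive_threshold(vals) == pytest.approx(brute, rel=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1e6, allow_nan=False), min_size=1, max_size=200))
    def test_equals_factor_times_mean_for_any_history(self, history):
        expected = 1.25 * float(np.mean(history))
        assert eb.adaptive_threshold(history) == pytest.approx(expected, rel=1e-9,
                                                               abs=1e-12)

    def test_window_keeps_only_last_200(self):
        history = [100.0] * 50 + [1.0] * 200
        assert eb.adaptive_threshold(history) == pytest.approx(1.25)

    def test_empty_history_raises(self):
        with pytest.raises(ValueError):
            eb.adaptive_threshold([])


class TestSwtDetail:
    def test_zero_signal_zero_coefficients(self):
        out = eb.swt_detail(np.zeros(1000))
        assert np.allclose(out, 0.0)
        assert out.size == 1000

    def test_length_preserved_for_awkward_sizes(self):
        for n in (997, 1024, 1531):
            assert eb.swt_detail(np.random.default_rng(0).normal(size=n)).size == n

    def test_s_deflection_localized(self):
        """The cd4^2 maximum falls within 40 ms of a lone S deflection."""
        tpl = eb.equine_template()
        x = np.zeros(5000)
        center = 2500
        start = center - tpl.peak_offset
        x[start:start + tpl.waveform.size] = tpl.waveform
        cd2 = eb.swt_detail(x)
        assert abs(int(np.argmax(cd2)) - center) <= 0.040 * RATE

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            eb.swt_detail(np.zeros(8))


class TestScanAndRefractory:
    def test_largest_of_two_close_maxima_wins(self):
        """Two suprathreshold maxima 150 ms apart: only the larger is kept."""
        idx = np.array([1000, 1075])  # 150 ms at 500 Hz
        vals = np.array([5.0, 3.0])
        res = _scan_maxima(idx, vals, RATE, DetectorConfig(),
                           seed_history=[1.0])
        assert list(res.peak_indices) == [1000]
        res2 = _scan_maxima(idx, vals[::-1].copy(), RATE, DetectorConfig(),
                            seed_history=[1.0])
        assert list(res2.peak_indices) == [1075]

    def test_flat_zero_signal_no_detections(self):
        res = eb.detect_speaks(np.zeros(5000), RATE)
        assert len(res) == 0

    def test_clean_record_perfect_score(self):
        rec = eb.generate_record(
            eb.equine_template(),
            eb.RhythmSpec(base_heart_rate=60, duration=60, seed=5))
        f = filtered_lead(rec)
        res = eb.detect_speaks(f, RATE)
        score = eb.score_detections(res.peak_indices, rec.annotation_indices(),
                                    RATE, 0.05)
        assert score.recall == 100.0
        assert score.ppv == 100.0

    def test_scale_equivariance(self):
        rec = eb.generate_record(
            eb.equine_template(),
            eb.RhythmSpec(base_heart_rate=60, duration=30, seed=9),
            eb.NOISE_PRESETS["clinic"])
        f = filtered_lead(rec)
        a = 7.3
        assert np.allclose(eb.swt_detail(a * f), a ** 2 * eb.swt_detail(f))
        d1 = eb.detect_speaks(f, RATE)
        d2 = eb.detect_speaks(a * f, RATE)
        assert np.array_equal(d1.peak_indices, d2.peak_indices)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_refractory_invariant(self, seed):
        rec = eb.generate_record(
            eb.equine_template(),
            eb.RhythmSpec(base_heart_rate=120 + 40 * seed, duration=20,
                          seed=seed, vpc_rate=4, artefact_rate=3),
            eb.NOISE_PRESETS["exercise"])
        res = eb.detect_speaks(filtered_lead(rec), RATE)
        if len(res) > 1:
            assert np.min(np.diff(res.peak_indices)) > 0.200 * RATE


class TestPanTompkins:
    def test_flat_zero_signal(self):
        assert len(eb.pan_tompkins(np.zeros(5000), RATE)) == 0

    def test_clean_human_record_full_recall(self):
        rec = eb.generate_record(
            eb.human_template(),
            eb.RhythmSpec(base_heart_rate=60, duration=60, seed=2))
        f = filtered_lead(rec)
        score = eb.score_detections(eb.pan_tompkins(f, RATE).peak_indices,
                                    rec.annotation_indices(), RATE, 0.05)
        assert score.recall == 100.0

    def test_tall_t_equine_record_trips_pan_tompkins(self):
        """Peaked tall T waves: Pan-Tompkins PPV drops below the SWT detector's."""
        rec = eb.generate_record(
            tall_t_equine_template(),
            eb.RhythmSpec(base_heart_rate=40, duration=120, seed=3))
        f = filtered_lead(rec)
        ref = rec.annotation_indices()
        swt = eb.score_detections(eb.detect_speaks(f, RATE).peak_indices, ref,
                                  RATE, 0.05)
        pt = eb.score_detections(eb.pan_tompkins(f, RATE).peak_indices, ref,
                                 RATE, 0.05)
        assert pt.ppv < swt.ppv


class TestScoring:
    def test_identical_lists(self):
        ref = np.arange(100, 5000, 400)
        s = eb.score_detections(ref, ref, RATE, 0.05)
        assert (s.false_positive, s.false_negative) == (0, 0)
        assert s.ppv == 100.0 and s.recall == 100.0

    def test_one_spurious_detection(self):
        ref = np.arange(100, 5000, 400)
        det = np.sort(np.append(ref, 4750))
        s = eb.score_detections(det, ref, RATE, 0.05)
        assert s.false_positive == 1 and s.false_negative == 0

    def test_published_detection_table_formula(self):
        """98.0% recall / 99.1% PPV from 10356 beats, 204 missed, 94 spurious."""
        s = eb.DetectionScore(true_positive=10356 - 204, false_positive=94,
                              false_negative=204, match_tolerance=0.05)
        assert round(s.recall, 1) == 98.0
        assert round(s.ppv, 1) == 99.1
        assert s.recall == pytest.approx(100 * (10356 - 204) / 10356)

    def test_negative_tolerance_raises(self):
        with pytest.raises(ValueError):
            eb.score_detections([1], [1], RATE, -0.01)
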