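"""Preprocessing rules: segmentation, beat filters, outlier pipeline,
respiratory filtering/resampling and the two normalization schemes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somnoscreen import preprocess as pp
from somnoscreen.preprocess import PatientStats


class TestSegmentation:
    def test_whole_night_epoch_count(self):
        x = np.zeros(8 * 3600 * 4)  # 8 h at 4 Hz
        assert pp.segment_signal(x, 4.0).shape == (960, 120)

    def test_trailing_partial_epoch_dropped(self):
        x = np.arange(45 * 4)  # 45 s at 4 Hz
        out = pp.segment_signal(x, 4.0)
        assert out.shape == (1, 120)
        assert out[0, -1] == 119

    def test_beats_half_open_convention(self):
        epochs = pp.segment_beats(np.array([5.0, 35.0, 65.0]), duration=90.0)
        assert [list(e) for e in epochs] == [[5.0], [35.0], [65.0]]

    def test_sub_epoch_recording_empty(self):
        assert pp.segment_beats(np.array([1.0]), duration=20.0) == []
        assert pp.segment_signal(np.zeros(10), 4.0).shape[0] == 0


class TestBeatRules:
    @pytest.mark.parametrize("n,keep", [(14, False), (15, True), (0, False), (40, True)])
    def test_min_beats_boundary(self, n, keep):
        assert pp.min_beats_filter(np.arange(n, dtype=float)) is keep

    def test_border_adjustment_first_beat(self):
        out, adjusted = pp.adjust_border_beats(np.array([0.2, 1.0, 1.8, 2.8]))
        assert adjusted
        assert out[0] == pytest.approx(1.0 - 0.5 * (0.8 + 1.0))
        assert np.allclose(out[1:-1], [1.0, 1.8])

    def test_border_adjustment_last_beat(self):
        out, _ = pp.adjust_border_beats(np.array([0.0, 1.0, 2.0, 3.0, 3.9]))
        assert out[-1] == pytest.approx(3.0 + 0.5 * (1.0 + 1.0))

    def test_regular_beats_unchanged(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        out, _ = pp.adjust_border_beats(t)
        assert np.allclose(out, t)

    def test_too_few_beats_left_unmodified(self):
        t = np.array([0.0, 1.0, 2.0])
        out, adjusted = pp.adjust_border_beats(t)
        assert not adjusted
        assert np.array_equal(out, t)

    def test_hr_from_rr(self):
        assert np.allclose(pp.beats_to_hr(np.array([0.0, 0.5, 1.0])), [120.0, 120.0])
        assert np.allclose(pp.beats_to_hr(np.array([0.0, 0.75, 1.5])), [80.0, 80.0])
        with pytest.raises(ValueError):
            pp.beats_to_hr(np.array([0.0, 1.0, 1.0]))


def brute_force_outliers(seg: np.ndarray) -> np.ndarray:
    """Independent per-sample evaluation of the three outlier rules."""
    med = float(np.median(seg))
    sd = float(np.std(seg))
    out = np.zeros(seg.size, dtype=bool)
    for i, v in enumerate(seg):
        rule_range = v < 40.0 or v > 180.0
        rule_median = abs(v - med) > 20.0
        rule_sd = abs(v - med) > 3.0 * sd
        out[i] = rule_range or rule_median or rule_sd
    return out


class TestOutlierPipeline:
    def test_constant_segment_clean(self):
        assert not pp.detect_hr_outliers(np.full(120, 60.0)).any()

    def test_median_band_rule_fires_inside_absolute_range(self):
        seg = np.full(120, 60.0)
        seg[50] = 85.0  # inside 40-180 but > median + 20
        assert pp.detect_hr_outliers(seg)[50]

    def test_absolute_range_rule(self):
        seg = np.full(120, 100.0)
        seg[3] = 190.0
        assert pp.detect_hr_outliers(seg)[3]

    def test_union_matches_brute_force_on_random_segments(self, rng):
        for _ in range(200):
            seg = rng.normal(rng.uniform(50, 150), rng.uniform(0.5, 30), 120)
            assert np.array_equal(pp.detect_hr_outliers(seg), brute_force_outliers(seg))

    def test_mirror_fill_three_sample_gap(self):
        seg = np.arange(120, dtype=float)
        mask = np.zeros(120, dtype=bool)
        mask[10:13] = True
        out, reason = pp.correct_or_reject(seg, mask)
        assert reason == ""
        assert list(out[10:13]) == [9.0, 8.0, 7.0]
        assert np.array_equal(out[:10], seg[:10]) and np.array_equal(out[13:], seg[13:])

    def test_run_longer_than_ten_samples_rejects(self):
        mask = np.zeros(120, dtype=bool)
        mask[20:31] = True  # 11 samples = 2.75 s at 4 Hz
        out, reason = pp.correct_or_reject(np.zeros(120), mask)
        assert out is None and reason == pp.REASON_LONG_OUTLIER

    def test_ten_sample_run_still_corrected(self):
        mask = np.zeros(120, dtype=bool)
        mask[20:30] = True
        out, reason = pp.correct_or_reject(np.arange(120.0), mask)
        assert reason == "" and list(out[20:30]) == list(np.arange(10, 20)[::-1])

    def test_empty_mask_identity(self):
        seg = np.arange(120.0)
        out, reason = pp.correct_or_reject(seg, np.zeros(120, dtype=bool))
        assert np.array_equal(out, seg) and reason == ""

    def test_gap_at_start_mirrors_following(self):
        seg = np.arange(120.0)
        mask = np.zeros(120, dtype=bool)
        mask[0:3] = True
        out, reason = pp.correct_or_reject(seg, mask)
        assert reason == ""
        assert list(out[0:3]) == [5.0, 4.0, 3.0]


class TestBuildTachogram:
    STATS = PatientStats(median_hr=60.0, median_resp=0.0, sd_resp=1.0)

    def test_constant_hr_gives_zeros(self):
        beats = np.arange(0.0, 31.0, 1.0)  # 31 beats at 60 BPM in epoch 0
        seg = pp.build_tachogram(beats, 0, self.STATS)
        assert not seg.rejected
        assert np.allclose(seg.values, 0.0)

    def test_monotone_hr_trend(self):
        # HR ramps 60 -> 80 across the epoch
        t, beats = 0.0, []
        while t < 31.0:
            beats.append(t)
            t += 60.0 / (60.0 + 20.0 * min(t / 30.0, 1.0))
        seg = pp.build_tachogram(np.array(beats), 0, self.STATS)
        assert not seg.rejected
        # border re-anchoring may bump the first interval's HR slightly
        assert np.all(np.diff(seg.values) >= -0.1)
        assert seg.values[0] == pytest.approx(0.0, abs=2.0)
        assert seg.values[-1] == pytest.approx(20.0, abs=2.0)

    def test_min_beats_rejection_propagates(self):
        seg = pp.build_tachogram(np.arange(0.0, 28.0, 2.5), 0, self.STATS)
        assert seg.rejected and seg.reason == pp.REASON_MIN_BEATS and seg.values is None


class TestRespiratoryChain:
    def test_passband_sinusoid_preserved(self):
        fs, t = 32.0, np.arange(0, 600, 1 / 32.0)
        x = np.sin(2 * np.pi * 0.25 * t)
        y = pp.filter_respiration(x, fs)
        mid = slice(int(100 * fs), int(500 * fs))
        assert np.ptp(y[mid]) == pytest.approx(np.ptp(x[mid]), rel=0.05)

    def test_dc_killed(self):
        y = pp.filter_respiration(np.full(32 * 600, 5.0), 32.0)
        assert np.max(np.abs(y)) < 1e-6 * 5.0

    @pytest.mark.parametrize("freq", [0.005, 10.0])
    def test_stopband_attenuated(self, freq):
        fs = 32.0
        t = np.arange(0, 1200, 1 / fs)
        y = pp.filter_respiration(np.sin(2 * np.pi * freq * t), fs)
        mid = slice(int(300 * fs), int(900 * fs))
        assert np.max(np.abs(y[mid])) <= 0.1

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            pp.filter_respiration(np.zeros(100), 4.0)

    def test_resample_ratio_and_fidelity(self):
        fs = 32.0
        t = np.arange(0, 120, 1 / fs)
        x = np.sin(2 * np.pi * 0.25 * t)
        y = pp.resample_4hz(x, fs)
        assert y.size == x.size // 8
        ref = np.sin(2 * np.pi * 0.25 * np.arange(y.size) / 4.0)
        inner = slice(20, -20)
        r = np.corrcoef(y[inner], ref[inner])[0, 1]
        assert r > 0.99

    def test_resample_identity_at_4hz(self):
        x = np.arange(120.0)
        assert np.array_equal(pp.resample_4hz(x, 4.0), x)


class TestNormalization:
    def test_sd_scheme_hand_arithmetic(self):
        stats = PatientStats(median_hr=60.0, median_resp=2.0, sd_resp=2.0)
        seg = pp.normalize_sd(np.array([4.0, 4.0, 6.0]), stats)
        assert np.allclose(seg.values, [0.0, 0.0, 1.0])

    def test_sd_scheme_median_zero(self, rng):
        stats = PatientStats(median_hr=60.0, median_resp=0.3, sd_resp=1.7)
        for _ in range(20):
            seg = pp.normalize_sd(rng.normal(0, 2, 120), stats)
            assert np.median(seg.values) == pytest.approx(0.0, abs=1e-12)

    def test_sd_scheme_degenerate_recording(self):
        with pytest.raises(ValueError):
            pp.normalize_sd(np.ones(120), PatientStats(60.0, 1.0, 0.0))

    def test_minmax_examples(self):
        assert np.allclose(pp.normalize_minmax(np.array([1.0, 2.0, 3.0])).values, [-0.5, 0.0, 0.5])
        assert np.allclose(pp.normalize_minmax(np.array([0.0, 10.0])).values, [-0.5, 0.5])

    def test_minmax_constant_flagged_zeros(self):
        seg = pp.normalize_minmax(np.full(120, 3.0))
        assert seg.constant_input and np.allclose(seg.values, 0.0)

    @given(
        a=st.floats(0.1, 50.0),
        b=st.floats(-100.0, 100.0),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_minmax_affine_invariant_sd_not(self, a, b, seed):
        x = np.random.default_rng(seed).normal(0, 1, 120)
        y = a * x + b
        assert np.allclose(
            pp.normalize_minmax(x).values, pp.normalize_minmax(y).values, atol=1e-8
        )
        stats = PatientStats(60.0, 0.0, 1.0)
        if abs(a - 1.0) > 0.1:
            assert not np.allclose(
                pp.normalize_sd(x, stats).values, pp.normalize_sd(y, stats).values, atol=1e-3
            )

    def test_minmax_range_exact(self, rng):
        for _ in range(50):
            v = pp.normalize_minmax(rng.normal(0, rng.uniform(0.1, 10), 120)).values
            assert v.min() == -0.5 and v.max() == 0.5


class TestQualityGateAndRecording:
    def test_gate_modes(self):
        retained = np.array([True, True, True])
        flags = np.array([True, False, True])
        assert list(pp.quality_gate(retained, flags, "clean")) == [True, False, True]
        assert list(pp.quality_gate(retained, flags, "full")) == [True, True, True]
        with pytest.raises(ValueError):
            pp.quality_gate(retained, flags, "bogus")

    def test_recording_vectors_are_120_samples(self, tiny_recording):
        ed = pp.preprocess_recording(tiny_recording)
        assert ed.X_resp.shape == (tiny_recording.n_epochs, 120)
        assert ed.X_card.shape == (tiny_recording.n_epochs, 120)

    def test_rejection_bookkeeping_conserved(self, tiny_recording):
        ed = pp.preprocess_recording(tiny_recording)
        n_kept = int(ed.retained_card.sum())
        n_rejected = sum(1 for r in ed.card_reason if r)
        assert n_kept + n_rejected == ed.n_epochs
        for i, r in enumerate(ed.card_reason):
            assert (r == "") == bool(ed.retained_card[i])
            if r:
                assert r in (pp.REASON_MIN_BEATS, pp.REASON_LONG_OUTLIER, pp.REASON_DEGENERATE)

    def test_invalid_norm_rejected(self, tiny_recording):
        with pytest.raises(ValueError):
            pp.preprocess_recording(tiny_recording, norm="zscore")
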