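"""Generator contracts: hypnogram statistics, event placement, signal
morphology, artifact grading, cohort composition and determinism."""

import numpy as np
import pytest

from somnoscreen import synthgen
from somnoscreen.synthgen import CardiacParams, InfeasibleSpecError, RespParams
from somnoscreen.types import (
    ApneaEvent,
    ArtifactModel,
    CohortSpec,
    EPOCH_SECONDS,
    GROUP_AHI_BOUNDS,
    OBSTRUCTIVE_APNEA,
    PatientRecording,
    SLEEP,
    WAKE,
)


class TestGenerateHypnogram:
    def test_wake_fraction_near_target(self):
        hyp = synthgen.generate_hypnogram(960, 0.20, 1.0, seed=1)
        assert hyp.size == 960
        assert set(np.unique(hyp)) <= {SLEEP, WAKE}
        assert 0.15 <= np.mean(hyp == WAKE) <= 0.25

    @pytest.mark.parametrize("wf", [0.14, 0.20, 0.27])
    @pytest.mark.parametrize("seed", [0, 7])
    def test_wake_fraction_tolerance_long_nights(self, wf, seed):
        hyp = synthgen.generate_hypnogram(960, wf, 1.0, seed=seed)
        assert abs(np.mean(hyp == WAKE) - wf) <= 0.05

    def test_vanishing_wake_fraction_gives_all_sleep(self):
        hyp = synthgen.generate_hypnogram(10, 1e-9, 1.0, seed=4)
        assert np.all(hyp == SLEEP)

    def test_fragmentation_scales_stage_changes(self):
        changes = {
            f: int(np.sum(np.diff(synthgen.generate_hypnogram(960, 0.2, f, seed=1)) != 0))
            for f in (1.0, 5.0)
        }
        assert changes[5.0] >= 2 * changes[1.0]

    def test_deterministic_under_seed(self):
        a = synthgen.generate_hypnogram(600, 0.2, 2.0, seed=9)
        b = synthgen.generate_hypnogram(600, 0.2, 2.0, seed=9)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_epochs": 0, "wake_fraction": 0.2},
            {"n_epochs": -5, "wake_fraction": 0.2},
            {"n_epochs": 10, "wake_fraction": 0.0},
            {"n_epochs": 10, "wake_fraction": 1.0},
            {"n_epochs": 10, "wake_fraction": 0.2, "fragmentation": 0.0},
        ],
    )
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            synthgen.generate_hypnogram(**kwargs)


class TestPlaceEvents:
    def test_count_on_all_sleep_night(self):
        hyp = np.zeros(960, dtype=np.int8)
        events = synthgen.place_events(hyp, 30.0, 0.5, 10, 30, seed=1)
        assert abs(len(events) - 240) <= 24

    def test_zero_ahi_empty(self):
        hyp = synthgen.generate_hypnogram(240, 0.2, 1.0, seed=2)
        assert synthgen.place_events(hyp, 0.0, seed=2) == []

    def test_events_confined_to_sleep_and_disjoint(self):
        hyp = synthgen.generate_hypnogram(960, 0.2, 1.0, seed=2)
        events = synthgen.place_events(hyp, 60.0, 0.5, 10, 30, seed=2)
        sleep_hours = np.sum(hyp == SLEEP) * EPOCH_SECONDS / 3600
        assert abs(len(events) - 60 * sleep_hours) <= 0.1 * 60 * sleep_hours
        for ev in events:
            first = int(ev.onset // EPOCH_SECONDS)
            last = int(np.ceil(ev.end / EPOCH_SECONDS)) - 1
            assert np.all(hyp[first : last + 1] == SLEEP)
        ordered = sorted(events, key=lambda e: e.onset)
        for a, b in zip(ordered, ordered[1:]):
            assert a.end <= b.onset

    @pytest.mark.parametrize("ahi", [5.0, 15.0, 45.0])
    def test_realized_ahi_within_ten_percent(self, ahi):
        hyp = synthgen.generate_hypnogram(960, 0.2, 1.0, seed=11)
        events = synthgen.place_events(hyp, ahi, seed=11)
        sleep_hours = np.sum(hyp == SLEEP) * EPOCH_SECONDS / 3600
        assert abs(len(events) / sleep_hours - ahi) <= 0.1 * ahi

    def test_all_wake_night_infeasible(self):
        with pytest.raises(InfeasibleSpecError):
            synthgen.place_events(np.ones(120, dtype=np.int8), 10.0, seed=0)

    def test_invalid_durations(self):
        hyp = np.zeros(120, dtype=np.int8)
        with pytest.raises(ValueError):
            synthgen.place_events(hyp, 10.0, min_dur=5.0, seed=0)


class TestSynthBeats:
    def test_deterministic_limit_regular_beats(self):
        p = CardiacParams(hr_sleep=60.0, hr_sd=0.0)
        beats = synthgen.synth_beats(np.zeros(1, dtype=np.int8), [], p, seed=0)
        assert beats.size == 30
        assert np.allclose(np.diff(beats), 1.0)

    def test_event_bradycardia_then_tachycardia(self):
        p = CardiacParams(hr_sleep=60.0, hr_sd=0.0, event_dip=10.0, event_overshoot=20.0)
        ev = [ApneaEvent(onset=30.0, duration=20.0, kind=OBSTRUCTIVE_APNEA)]
        beats = synthgen.synth_beats(np.zeros(3, dtype=np.int8), ev, p, seed=0)
        hr = 60.0 / np.diff(beats)
        mid = 0.5 * (beats[1:] + beats[:-1])
        window = (mid >= 30.0) & (mid <= 50.0 + p.recovery_s)
        assert hr[window].min() < 60.0 - 5.0
        assert hr[window].max() > 60.0 + 10.0

    def test_gap_bounds_and_seed_contract(self, tiny_recording):
        gaps = np.diff(tiny_recording.beat_times)
        assert np.all(gaps > 0.33) and np.all(gaps < 1.5)
        hyp = tiny_recording.hypnogram
        a = synthgen.synth_beats(hyp, tiny_recording.events, seed=5)
        b = synthgen.synth_beats(hyp, tiny_recording.events, seed=5)
        c = synthgen.synth_beats(hyp, tiny_recording.events, seed=6)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_stage_dependent_mean_hr(self):
        hyp = synthgen.generate_hypnogram(240, 0.3, 1.0, seed=3)
        beats = synthgen.synth_beats(hyp, [], seed=3)
        hr = 60.0 / np.diff(beats)
        epoch = (0.5 * (beats[1:] + beats[:-1]) // EPOCH_SECONDS).astype(int)
        wake_hr = hr[hyp[epoch] == WAKE].mean()
        sleep_hr = hr[hyp[epoch] == SLEEP].mean()
        assert wake_hr > sleep_hr + 5.0


class TestSynthRespiration:
    def test_spectral_peak_at_breathing_rate(self):
        p = RespParams(rate_sleep=15.0, rate_sd_sleep=0.0, amp_mod_sleep=0.0, noise_sd=0.0)
        sig, fs = synthgen.synth_respiration(np.zeros(1, dtype=np.int8), [], p, seed=0)
        freqs = np.fft.rfftfreq(sig.size, 1 / fs)
        spec = np.abs(np.fft.rfft(sig))
        assert abs(freqs[np.argmax(spec)] - 0.25) < 0.02

    def test_apnea_epoch_is_flat(self):
        ev = [ApneaEvent(onset=25.0, duration=40.0, kind=OBSTRUCTIVE_APNEA)]
        sig, fs = synthgen.synth_respiration(np.zeros(3, dtype=np.int8), ev, seed=1)
        spe = int(EPOCH_SECONDS * fs)
        rms = lambda x: float(np.sqrt(np.mean(x**2)))
        baseline = rms(sig[2 * spe :])  # event-free epoch
        inside = rms(sig[spe : int(60.0 * fs)])  # fully inside the apnea
        assert inside <= 0.05 * baseline

    def test_event_free_recording_has_no_cessation(self):
        hyp = synthgen.generate_hypnogram(240, 0.2, 1.0, seed=5)
        sig, fs = synthgen.synth_respiration(hyp, [], seed=5)
        spe = int(EPOCH_SECONDS * fs)
        rms = np.sqrt((sig[: 240 * spe].reshape(240, spe) ** 2).mean(axis=1))
        for stage in (SLEEP, WAKE):
            r = rms[hyp == stage]
            assert r.min() >= 0.4 * np.median(r)

    def test_sleep_breathing_deeper_than_wake(self):
        hyp = synthgen.generate_hypnogram(240, 0.3, 1.0, seed=6)
        sig, fs = synthgen.synth_respiration(hyp, [], seed=6)
        spe = int(EPOCH_SECONDS * fs)
        rms = np.sqrt((sig[: 240 * spe].reshape(240, spe) ** 2).mean(axis=1))
        assert rms[hyp == SLEEP].mean() > rms[hyp == WAKE].mean()

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            RespParams(fs=3.0)


class TestCorruptAndGrade:
    def test_artifact_free_model_grades_all_high(self, tiny_recording):
        m = ArtifactModel(
            motion_burst_rate_wake=0.0,
            motion_burst_rate_sleep=0.0,
            post_apnea_burst_prob=0.0,
            drift_amplitude=0.0,
        )
        out = synthgen.corrupt_and_grade(tiny_recording, m, seed=1)
        assert np.all(out.quality["resp"]) and np.all(out.quality["cardiac"])
        assert np.allclose(out.resp_signal, tiny_recording.resp_signal)

    def test_certain_post_apnea_burst_degrades_terminating_epoch(self, tiny_recording):
        m = ArtifactModel(post_apnea_burst_prob=1.0)
        out = synthgen.corrupt_and_grade(tiny_recording, m, seed=2)
        for ev in tiny_recording.events:
            term = min(int(ev.end // EPOCH_SECONDS), out.n_epochs - 1)
            nxt = min(term + 1, out.n_epochs - 1)
            # the 1-3 s restoration burst starts at the event end and may
            # straddle the epoch boundary
            assert not (out.quality["resp"][term] and out.quality["resp"][nxt])

    def test_sev_cohort_quality_ordering(self):
        spec = CohortSpec(
            n_per_group={"No": 0, "Mild": 0, "Mod": 0, "Sev": 10},
            recording_hours=2.0,
            seed=3,
        )
        cohort = synthgen.generate_cohort(spec)
        low_wake, low_sleep, low_apn, low_noapn = [], [], [], []
        for rec in cohort:
            low = ~rec.quality["resp"]
            apn = rec.apnea_epoch_mask()
            wake = rec.hypnogram == WAKE
            low_wake.append(low[wake].mean())
            low_sleep.append(low[~wake].mean())
            low_apn.append(low[apn].mean())
            low_noapn.append(low[~apn & ~wake].mean())
        assert np.mean(low_wake) > np.mean(low_sleep)
        assert np.mean(low_apn) > np.mean(low_noapn)

    def test_invariant_wake_rate_exceeds_sleep_rate(self):
        with pytest.raises(ValueError):
            ArtifactModel(motion_burst_rate_wake=1.0, motion_burst_rate_sleep=2.0)


class TestGenerateCohort:
    def test_composition_and_class_consistent_ahis(self):
        spec = CohortSpec(
            n_per_group={"No": 2, "Mild": 1, "Mod": 2, "Sev": 2},
            recording_hours=1.0,
            seed=10,
        )
        cohort = synthgen.generate_cohort(spec)
        assert len(cohort) == 7
        for rec in cohort:
            lo, hi = GROUP_AHI_BOUNDS[rec.group]
            assert lo <= rec.ahi <= hi
            assert isinstance(rec, PatientRecording)
            sleep_hours = rec.sleep_hours
            realized = len(rec.events) / sleep_hours
            if rec.ahi >= 5:
                assert abs(realized - rec.ahi) <= 0.15 * rec.ahi

    def test_empty_spec_gives_empty_cohort(self):
        spec = CohortSpec(n_per_group={"No": 0, "Mild": 0, "Mod": 0, "Sev": 0}, seed=0)
        assert synthgen.generate_cohort(spec) == []

    def test_same_seed_identical_cohorts(self):
        spec = CohortSpec(
            n_per_group={"No": 1, "Mild": 0, "Mod": 0, "Sev": 1}, recording_hours=1.0, seed=4
        )
        a = synthgen.generate_cohort(spec)
        b = synthgen.generate_cohort(spec)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.beat_times, rb.beat_times)
            assert np.array_equal(ra.resp_signal, rb.resp_signal)
            assert np.array_equal(ra.hypnogram, rb.hypnogram)
            assert ra.events == rb.events
            assert ra.ahi == rb.ahi
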