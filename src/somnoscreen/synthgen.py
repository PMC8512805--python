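"""Synthetic cardiorespiratory cohort generator.

Emulates the statistical structure the downstream analysis exploits in real
suspected-OSA cohorts:

* binary hypnograms with a controllable wake fraction (default 14-27 % of
  the night) and a sleep-fragmentation knob,
* AHI-controlled obstructive apnea/hypopnea events confined to sleep,
* stage-dependent heart-rate and respiratory dynamics, with the
  bradycardia-then-tachycardia signature around apneas,
* breathing cessation (apnea) and amplitude reduction (hypopnea) in the
  effort signal,
* movement artifacts concentrated in wake and at apnea terminations, and
  the per-epoch high/low quality grading they induce in a
  capacitive-sensor-like recording.

Everything is deterministic under a seed; distinct patients draw from
independent named substreams of the cohort seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from somnoscreen.types import (
    ApneaEvent,
    ArtifactModel,
    CohortSpec,
    EPOCH_SECONDS,
    GROUP_AHI_BOUNDS,
    OBSTRUCTIVE_APNEA,
    OBSTRUCTIVE_HYPOPNEA,
    PatientRecording,
    SLEEP,
    WAKE,
    group_for_ahi,
)

__all__ = [
    "CardiacParams",
    "RespParams",
    "InfeasibleSpecError",
    "generate_hypnogram",
    "place_events",
    "synth_beats",
    "synth_respiration",
    "corrupt_and_grade",
    "generate_cohort",
    "generate_low_ahi_cohort",
]


class InfeasibleSpecError(ValueError):
    """Raised when a requested configuration cannot be realized."""


#: per-epoch switching intensity of the hypnogram chain at fragmentation 1
_BASE_SWITCH = 0.10
#: bounded resampling: accept the first hypnogram draw within this many
#: percentage points of the target wake fraction (recordings of >= 200 epochs)
_WAKE_TOL = 0.04
_MAX_DRAWS = 50


def generate_hypnogram(
    n_epochs: int,
    wake_fraction: float,
    fragmentation: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate a binary per-epoch hypnogram.

    A two-state Markov chain over {sleep, wake} whose stationary wake
    probability equals ``wake_fraction`` and whose switching intensity
    scales linearly with ``fragmentation``. For recordings of at least 200
    epochs the draw is repeated (bounded, deterministic) until the
    empirical wake share is within 4 percentage points of the target, so
    short-night sampling noise cannot produce an unrepresentative cohort.

    Returns an ``int8`` array of length ``n_epochs`` over {SLEEP, WAKE}.
    """
    if n_epochs <= 0:
        raise ValueError(f"n_epochs must be positive, got {n_epochs}")
    if not 0.0 < wake_fraction < 1.0:
        raise ValueError(f"wake_fraction must be in (0, 1), got {wake_fraction}")
    if fragmentation <= 0:
        raise ValueError(f"fragmentation must be positive, got {fragmentation}")
    rng = np.random.default_rng(seed)

    c = _BASE_SWITCH * fragmentation
    p_sw = min(c * wake_fraction, 1.0)  # P(sleep -> wake)
    p_ws = min(c * (1.0 - wake_fraction), 1.0)  # P(wake -> sleep)

    best: np.ndarray | None = None
    best_err = np.inf
    n_draws = _MAX_DRAWS if n_epochs >= 200 else 1
    for _ in range(n_draws):
        u = rng.random(n_epochs)
        seq = np.empty(n_epochs, dtype=np.int8)
        state = WAKE if u[0] < wake_fraction else SLEEP  # stationary start
        seq[0] = state
        for i in range(1, n_epochs):
            flip = u[i] < (p_sw if state == SLEEP else p_ws)
            if flip:
                state = WAKE if state == SLEEP else SLEEP
            seq[i] = state
        err = abs(float(np.mean(seq == WAKE)) - wake_fraction)
        if err < best_err:
            best, best_err = seq, err
        if err <= _WAKE_TOL:
            break
    assert best is not None
    return best


def _sleep_runs(hypnogram: np.ndarray) -> list[tuple[float, float]]:
    """Maximal runs of contiguous sleep epochs as [start_s, end_s) intervals."""
    hyp = np.asarray(hypnogram)
    sleep = np.flatnonzero(hyp == SLEEP)
    if sleep.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(sleep) > 1)
    starts = np.concatenate(([sleep[0]], sleep[breaks + 1]))
    ends = np.concatenate((sleep[breaks], [sleep[-1]])) + 1
    return [(s * EPOCH_SECONDS, e * EPOCH_SECONDS) for s, e in zip(starts, ends)]


def place_events(
    hypnogram: np.ndarray,
    ahi: float,
    mix: float = 0.5,
    min_dur: float = 10.0,
    max_dur: float = 30.0,
    seed: int | np.random.Generator = 0,
    min_gap: float = 5.0,
) -> list[ApneaEvent]:
    """Place non-overlapping obstructive events inside sleep at a target AHI.

    ``ahi`` is events per hour of sleep (sleep epochs x 30 s); ``mix`` is
    the fraction of hypopneas among events. Events are drawn with uniform
    duration in ``[min_dur, max_dur]`` and placed uniformly inside the
    free space of contiguous sleep runs, keeping at least ``min_gap``
    seconds of recovered breathing between events.
    """
    if ahi < 0:
        raise ValueError(f"ahi must be non-negative, got {ahi}")
    if not (10.0 <= min_dur <= max_dur <= 60.0):
        raise ValueError("event durations must satisfy 10 <= min_dur <= max_dur <= 60 s")
    if not 0.0 <= mix <= 1.0:
        raise ValueError(f"mix must be in [0, 1], got {mix}")
    hyp = np.asarray(hypnogram)
    sleep_hours = float(np.sum(hyp == SLEEP)) * EPOCH_SECONDS / 3600.0
    if ahi == 0:
        return []
    if sleep_hours == 0:
        raise InfeasibleSpecError("cannot place events: hypnogram has no sleep epochs")
    rng = np.random.default_rng(seed)
    target = int(round(ahi * sleep_hours))

    free = _sleep_runs(hyp)
    events: list[ApneaEvent] = []
    for _ in range(target):
        dur = float(rng.uniform(min_dur, max_dur))
        candidates = [i for i, (s, e) in enumerate(free) if e - s >= dur]
        if not candidates:
            break
        lengths = np.array([free[i][1] - free[i][0] for i in candidates])
        i = candidates[rng.choice(len(candidates), p=lengths / lengths.sum())]
        s, e = free.pop(i)
        onset = float(rng.uniform(s, e - dur))
        kind = OBSTRUCTIVE_HYPOPNEA if rng.random() < mix else OBSTRUCTIVE_APNEA
        events.append(ApneaEvent(onset=onset, duration=dur, kind=kind))
        left = (s, onset - min_gap)
        right = (onset + dur + min_gap, e)
        for seg in (left, right):
            if seg[1] - seg[0] >= min_dur:
                free.append(seg)
    events.sort(key=lambda ev: ev.onset)
    return events


@dataclass
class CardiacParams:
    """Stage- and event-dependent heart-rate dynamics (BPM)."""

    hr_wake: float = 70.0
    hr_sleep: float = 58.0
    hr_sd: float = 2.0  # SD of the slow OU modulation of instantaneous HR
    hr_tau: float = 60.0  # OU correlation time, s
    event_dip: float = 12.0  # bradycardia depth reached at event end
    event_overshoot: float = 18.0  # tachycardia peak when breathing restores
    recovery_s: float = 10.0  # linear decay time of the overshoot
    hr_min: float = 42.0
    hr_max: float = 175.0

    def __post_init__(self) -> None:
        if self.hr_min <= 40.0 or self.hr_max >= 180.0:
            # keeps inter-beat gaps strictly inside [0.33, 1.5] s
            raise ValueError("hr_min/hr_max must lie strictly inside (40, 180) BPM")
        if self.hr_sd < 0 or self.hr_tau <= 0:
            raise ValueError("invalid HR variability parameters")


def _ou_series(n: int, sd: float, tau_samples: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck noise, unit-free, via an AR(1) filter."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    rho = float(np.exp(-1.0 / tau_samples))
    eps = rng.standard_normal(n)
    eps[0] /= np.sqrt(1.0 - rho**2)  # stationary start
    return sd * np.sqrt(1.0 - rho**2) * lfilter([1.0], [1.0, -rho], eps)


def _event_hr_delta(grid: np.ndarray, events: Sequence[ApneaEvent], p: CardiacParams) -> np.ndarray:
    """Bradycardia-then-tachycardia HR modulation on a time grid."""
    delta = np.zeros_like(grid)
    for ev in events:
        depth = p.event_dip if ev.kind == OBSTRUCTIVE_APNEA else 0.5 * p.event_dip
        peak = p.event_overshoot if ev.kind == OBSTRUCTIVE_APNEA else 0.5 * p.event_overshoot
        inside = (grid >= ev.onset) & (grid < ev.end)
        delta[inside] -= depth * (grid[inside] - ev.onset) / ev.duration
        rec = (grid >= ev.end) & (grid < ev.end + p.recovery_s)
        delta[rec] += peak * (1.0 - (grid[rec] - ev.end) / p.recovery_s)
    return delta


def synth_beats(
    hypnogram: np.ndarray,
    events: Sequence[ApneaEvent],
    params: CardiacParams | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Generate strictly increasing beat times for a whole recording.

    Instantaneous HR is the stage mean (wake vs sleep) plus a slow
    Ornstein-Uhlenbeck modulation, overlaid with a piecewise-linear
    bradycardia ramp inside each event and a tachycardia overshoot decaying
    over ``recovery_s`` after breathing is restored. Beats are integrated
    from the instantaneous rate; HR is clipped to ``[hr_min, hr_max]`` so
    inter-beat gaps stay inside (0.33, 1.5) s outside pathological input.
    """
    p = params or CardiacParams()
    rng = np.random.default_rng(seed)
    hyp = np.asarray(hypnogram)
    duration = hyp.size * EPOCH_SECONDS

    grid_hz = 4.0
    grid = np.arange(int(duration * grid_hz)) / grid_hz
    stage = hyp[np.minimum((grid // EPOCH_SECONDS).astype(int), hyp.size - 1)]
    hr = np.where(stage == WAKE, p.hr_wake, p.hr_sleep).astype(float)
    hr += _ou_series(grid.size, p.hr_sd, p.hr_tau * grid_hz, rng)
    hr += _event_hr_delta(grid, events, p)
    hr = np.clip(hr, p.hr_min, p.hr_max)

    beats = []
    t = float(rng.uniform(0.0, 60.0 / hr[0])) if p.hr_sd > 0 else 0.0
    while t < duration:
        beats.append(t)
        idx = min(int(t * grid_hz), hr.size - 1)
        t += 60.0 / hr[idx]
    return np.asarray(beats)


@dataclass
class RespParams:
    """Stage- and event-dependent respiratory-effort dynamics."""

    fs: float = 32.0  # Hz
    rate_wake: float = 17.0  # breaths/min
    rate_sleep: float = 13.0
    rate_sd_wake: float = 1.5  # breath-rate irregularity (OU SD, breaths/min)
    rate_sd_sleep: float = 0.4
    rate_tau: float = 20.0  # OU correlation time, s
    amp_wake: float = 0.9  # effort amplitude, arbitrary units
    amp_sleep: float = 1.3  # deeper breathing during sleep
    amp_mod_wake: float = 0.35  # fractional amplitude irregularity
    amp_mod_sleep: float = 0.08
    harmonic: float = 0.25  # second-harmonic share (breath asymmetry)
    hypopnea_factor: float = 0.5  # residual amplitude during hypopnea
    apnea_factor: float = 0.02  # residual amplitude during apnea (flat line)
    edge_s: float = 0.5  # cosine ramp at event boundaries
    noise_sd: float = 0.005  # sensor noise floor, signal units

    def __post_init__(self) -> None:
        if self.fs < 4.0:
            raise ValueError(f"resp_fs must be at least 4 Hz, got {self.fs}")


def _event_envelope(t: np.ndarray, events: Sequence[ApneaEvent], p: RespParams) -> np.ndarray:
    """Multiplicative amplitude envelope: cessation/reduction inside events."""
    env = np.ones_like(t)
    for ev in events:
        factor = p.apnea_factor if ev.kind == OBSTRUCTIVE_APNEA else p.hypopnea_factor
        inside = (t >= ev.onset) & (t < ev.end)
        if not inside.any():
            continue
        tt = t[inside]
        ramp_in = np.clip((tt - ev.onset) / p.edge_s, 0.0, 1.0)
        ramp_out = np.clip((ev.end - tt) / p.edge_s, 0.0, 1.0)
        depth = ramp_in * ramp_out if ev.duration < 2 * p.edge_s else np.minimum(ramp_in, ramp_out)
        env[inside] = np.minimum(env[inside], 1.0 - (1.0 - factor) * depth)
    return env


def synth_respiration(
    hypnogram: np.ndarray,
    events: Sequence[ApneaEvent],
    params: RespParams | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, float]:
    """Generate a quasi-sinusoidal respiratory-effort waveform.

    Breathing rate and amplitude are stage dependent (sleep is slower,
    deeper and more regular than wake); an obstructive apnea suppresses the
    waveform to a near-flat line (``apnea_factor`` of the local baseline)
    and a hypopnea reduces it to ``hypopnea_factor``, with short cosine
    ramps at the boundaries. Returns ``(signal, fs)``.
    """
    p = params or RespParams()
    rng = np.random.default_rng(seed)
    hyp = np.asarray(hypnogram)
    n = int(hyp.size * EPOCH_SECONDS * p.fs)
    t = np.arange(n) / p.fs
    stage = hyp[np.minimum((t // EPOCH_SECONDS).astype(int), hyp.size - 1)]
    wake = stage == WAKE

    rate = np.where(wake, p.rate_wake, p.rate_sleep).astype(float)
    rate_sd = np.where(wake, p.rate_sd_wake, p.rate_sd_sleep)
    rate = rate + rate_sd * _ou_series(n, 1.0, p.rate_tau * p.fs, rng)
    rate = np.clip(rate, 4.0, 40.0)
    cycles = np.cumsum(rate / 60.0) / p.fs
    phase = 2.0 * np.pi * np.mod(cycles, 1.0)  # wrapped: keeps sin() fast and accurate

    amp = np.where(wake, p.amp_wake, p.amp_sleep).astype(float)
    # smooth stage steps over ~2 s so epoch boundaries are not discontinuities
    k = max(int(2 * p.fs), 1)
    amp = np.convolve(amp, np.ones(k) / k, mode="same")
    amp_mod = np.where(wake, p.amp_mod_wake, p.amp_mod_sleep)
    amp = amp * (1.0 + amp_mod * _ou_series(n, 1.0, 5.0 * p.fs, rng))

    wave = np.sin(phase) + p.harmonic * np.sin(2.0 * phase + 0.6)
    signal = amp * _event_envelope(t, events, p) * wave
    signal += p.noise_sd * rng.standard_normal(n)
    return signal, p.fs


def _epoch_of(time_s: float, n_epochs: int) -> int:
    return min(max(int(time_s // EPOCH_SECONDS), 0), n_epochs - 1)


def corrupt_and_grade(
    recording: PatientRecording,
    artifact_model: ArtifactModel | None = None,
    seed: int | np.random.Generator = 0,
) -> PatientRecording:
    """Inject movement artifacts and grade per-epoch signal quality.

    Motion bursts (band-limited noise transients, 1-3 s, amplitude
    ``burst_amplitude_factor`` x the baseline effort amplitude) occur as a
    Poisson process with a stage-dependent rate, plus one burst with
    probability ``post_apnea_burst_prob`` at each apnea termination -- the
    large body movement when breathing is restored. A slow sinusoidal
    baseline drift is always present. An epoch's quality flag is ``low``
    exactly when the injected artifact energy inside it exceeds
    ``quality_energy_threshold``; the cardiac channel sees the same motion
    with gain ``cardiac_energy_gain``.

    Returns a new recording; the input is not modified.
    """
    m = artifact_model or ArtifactModel()
    rng = np.random.default_rng(seed)
    fs = recording.resp_fs
    resp = recording.resp_signal.copy()
    n_epochs = recording.n_epochs
    n = resp.size
    baseline = float(np.sqrt(2.0) * np.std(recording.resp_signal)) or 1.0

    energy = np.zeros(n_epochs)

    # slow baseline wander (10 min period, random phase)
    if m.drift_amplitude > 0:
        t = np.arange(n) / fs
        drift = m.drift_amplitude * baseline * np.sin(2 * np.pi * t / 600.0 + rng.uniform(0, 2 * np.pi))
        resp += drift
        for i in range(n_epochs):
            seg = drift[int(i * EPOCH_SECONDS * fs) : int((i + 1) * EPOCH_SECONDS * fs)]
            energy[i] += float(np.sum(seg**2) / fs)

    # stage-dependent motion bursts + post-apnea restoration bursts
    rate_per_epoch = np.where(
        recording.hypnogram == WAKE,
        m.motion_burst_rate_wake,
        m.motion_burst_rate_sleep,
    ) * (EPOCH_SECONDS / 3600.0)
    burst_onsets = []
    counts = rng.poisson(rate_per_epoch)
    for i in np.flatnonzero(counts):
        burst_onsets.extend(i * EPOCH_SECONDS + rng.uniform(0, EPOCH_SECONDS, counts[i]))
    for ev in recording.events:
        if rng.random() < m.post_apnea_burst_prob:
            burst_onsets.append(min(ev.end, n_epochs * EPOCH_SECONDS - 1.0))

    for onset in sorted(burst_onsets):
        dur = float(rng.uniform(1.0, 3.0))
        nb = int(dur * fs)
        start = int(onset * fs)
        nb = min(nb, n - start)
        # band-limit the transient to motion-like low frequencies (~0.5-3 Hz)
        k = max(int(fs / 6), 1)
        if nb <= k:
            continue  # truncated sliver at the recording edge
        shape = np.hanning(nb)
        noise = rng.standard_normal(nb)
        noise = np.convolve(noise, np.ones(k) / k, mode="same")
        # unit-RMS transient so burst_amplitude_factor is amplitude vs baseline
        noise /= max(float(np.sqrt(np.mean(noise**2))), 1e-12)
        burst = m.burst_amplitude_factor * baseline * shape * noise
        resp[start : start + nb] += burst
        # split the burst energy over the epochs it covers
        e0 = _epoch_of(onset, n_epochs)
        e1 = _epoch_of(onset + dur, n_epochs)
        for i in range(e0, e1 + 1):
            lo = max(start, int(i * EPOCH_SECONDS * fs))
            hi = min(start + nb, int((i + 1) * EPOCH_SECONDS * fs))
            if hi > lo:
                energy[i] += float(np.sum(burst[lo - start : hi - start] ** 2) / fs)

    quality = {
        "resp": energy <= m.quality_energy_threshold,
        "cardiac": energy * m.cardiac_energy_gain <= m.quality_energy_threshold,
    }
    return replace(recording, resp_signal=resp, quality=quality)


def _patient_recording(
    patient_id: str,
    ahi: float,
    wake_fraction: float,
    n_epochs: int,
    rng: np.random.Generator,
    cardiac: CardiacParams,
    resp: RespParams,
    artifact_model: ArtifactModel | None,
) -> PatientRecording:
    # per-patient physiological variation around the population defaults
    hr_wake = float(rng.normal(cardiac.hr_wake, 3.0))
    c = replace(cardiac, hr_wake=hr_wake, hr_sleep=hr_wake - float(rng.uniform(8.0, 14.0)))
    amp_scale = float(rng.uniform(0.8, 1.2))
    r = replace(
        resp,
        rate_wake=float(np.clip(rng.normal(resp.rate_wake, 1.0), 14.5, 22.0)),
        rate_sleep=float(np.clip(rng.normal(resp.rate_sleep, 0.7), 10.0, 14.4)),
        amp_wake=resp.amp_wake * amp_scale,
        amp_sleep=resp.amp_sleep * amp_scale,
    )
    # sleep fragmentation grows with OSA severity (arousals after events)
    fragmentation = 1.0 + ahi / 30.0
    hyp = generate_hypnogram(n_epochs, wake_fraction, fragmentation, rng)
    events = place_events(hyp, ahi, mix=0.5, seed=rng)
    beats = synth_beats(hyp, events, c, rng)
    signal, fs = synth_respiration(hyp, events, r, rng)
    rec = PatientRecording(
        patient_id=patient_id,
        beat_times=beats,
        resp_signal=signal,
        resp_fs=fs,
        hypnogram=hyp,
        events=events,
        quality={},
        ahi=ahi,
    )
    return corrupt_and_grade(rec, artifact_model, rng)


def generate_cohort(
    spec: CohortSpec,
    cardiac: CardiacParams | None = None,
    resp: RespParams | None = None,
    artifact_model: ArtifactModel | None = None,
) -> list[PatientRecording]:
    """Generate a cohort with the spec's per-group composition.

    Each patient's AHI is drawn uniformly within its severity-class bounds
    (severe capped at 100/h); wake fraction is uniform in
    ``spec.wake_fraction_range``. Deterministic under ``spec.seed``.
    """
    cardiac = cardiac or CardiacParams()
    resp = resp or RespParams()
    cohort: list[PatientRecording] = []
    idx = 0
    for group in ("No", "Mild", "Mod", "Sev"):
        lo, hi = GROUP_AHI_BOUNDS[group]
        for _ in range(spec.n_per_group.get(group, 0)):
            rng = np.random.default_rng([spec.seed, idx])
            ahi = float(rng.uniform(lo, hi))
            wf = float(rng.uniform(*spec.wake_fraction_range))
            rec = _patient_recording(
                f"P{idx:03d}", ahi, wf, spec.n_epochs, rng, cardiac, resp, artifact_model
            )
            rec.group = group
            cohort.append(rec)
            idx += 1
    return cohort


def generate_low_ahi_cohort(
    n_patients: int,
    seed: int = 0,
    recording_hours: float = 8.0,
    ahi_max: float = 10.0,
    wake_fraction_range: tuple[float, float] = (0.14, 0.27),
    cardiac: CardiacParams | None = None,
    resp: RespParams | None = None,
    artifact_model: ArtifactModel | None = None,
) -> list[PatientRecording]:
    """Generate a classifier-training pool of low-AHI patients.

    Sleep-wake networks are trained on patients with AHI below 10 so they
    learn stage patterns rather than apnea signatures; AHI is drawn
    uniformly in ``[0, ahi_max)``.
    """
    cardiac = cardiac or CardiacParams()
    resp = resp or RespParams()
    n_epochs = int(recording_hours * 3600.0 / EPOCH_SECONDS)
    cohort = []
    for idx in range(n_patients):
        rng = np.random.default_rng([seed, 1_000_000 + idx])
        ahi = float(rng.uniform(0.0, ahi_max))
        wf = float(rng.uniform(*wake_fraction_range))
        rec = _patient_recording(
            f"T{idx:03d}", ahi, wf, n_epochs, rng, cardiac, resp, artifact_model
        )
        rec.group = group_for_ahi(ahi)
        cohort.append(rec)
    return cohort
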