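"""Epoch-level preprocessing of beats and respiratory effort.

Turns a night of raw beat times and respiratory-effort samples into the
fixed-length inputs of the sleep-wake classifier: per 30 s epoch, a
120-sample tachogram (instantaneous heart rate interpolated on a 4 Hz
grid, outlier-corrected, patient-median-subtracted) and a 120-sample
normalized respiratory vector.

Cardiac chain, per epoch: drop epochs with fewer than 15 beats; re-anchor
the first and last beat by linear extrapolation from the neighbouring
intervals; HR = 60/R-R per beat; interpolate at 4 Hz; flag outliers
(outside 40-180 BPM, outside segment median +/- 20 BPM, or outside segment
median +/- 3 SD); fill outlier runs of at most 2.5 s by mirroring the
preceding samples, reject longer runs; subtract the patient's overall
median HR.

Respiratory chain: band-pass 0.04-2 Hz (Butterworth order 4, zero-phase),
downsample to 4 Hz, then either the sd scheme (subtract the patient's
overall median, divide by the patient's overall SD, subtract the segment
median) or the min-max scheme (scale every segment to [-0.5, 0.5]).
Patient-level statistics are computed over the full recording before any
epoch rejection.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
import logging

import numpy as np
from scipy import signal as sps

from somnoscreen.types import (
    EPOCH_GRID_HZ,
    EPOCH_SAMPLES,
    EPOCH_SECONDS,
    PatientRecording,
)

__all__ = [
    "TachogramSegment",
    "RespSegment",
    "PatientStats",
    "EpochData",
    "segment_signal",
    "segment_beats",
    "min_beats_filter",
    "adjust_border_beats",
    "beats_to_hr",
    "detect_hr_outliers",
    "correct_or_reject",
    "build_tachogram",
    "filter_respiration",
    "resample_4hz",
    "normalize_sd",
    "normalize_minmax",
    "quality_gate",
    "compute_patient_stats",
    "preprocess_recording",
]

logger = logging.getLogger(__name__)

MIN_BEATS = 15
HR_RANGE = (40.0, 180.0)  # BPM
HR_MEDIAN_BAND = 20.0  # BPM around the segment median
HR_SD_FACTOR = 3.0
MAX_GAP_SECONDS = 2.5  # longest correctable outlier run
BAND_HZ = (0.04, 2.0)
FILTER_ORDER = 4

REASON_MIN_BEATS = "min-beats"
REASON_LONG_OUTLIER = "long-outlier"
REASON_DEGENERATE = "degenerate"


@dataclass
class PatientStats:
    """Whole-recording normalization statistics (computed before rejection)."""

    median_hr: float  # BPM
    median_resp: float  # filtered-signal units
    sd_resp: float


@dataclass
class TachogramSegment:
    """One epoch's 4 Hz heart-rate vector, or its rejection record."""

    epoch_index: int
    values: np.ndarray | None  # 120 samples, patient-median-subtracted
    rejected: bool = False
    reason: str = ""


@dataclass
class RespSegment:
    """One epoch's normalized 4 Hz respiratory vector."""

    epoch_index: int
    values: np.ndarray
    scheme: str  # "sd" or "minmax"
    constant_input: bool = False


def segment_signal(x: np.ndarray, fs: float, epoch_length: float = EPOCH_SECONDS) -> np.ndarray:
    """Split a uniformly sampled signal into complete epochs.

    Returns an ``(n_epochs, epoch_length*fs)`` array; trailing samples that
    do not fill a whole epoch are dropped.
    """
    x = np.asarray(x)
    spe = int(round(epoch_length * fs))
    n_epochs = x.size // spe
    if n_epochs == 0:
        logger.warning("recording shorter than one epoch (%d samples)", x.size)
    return x[: n_epochs * spe].reshape(n_epochs, spe)


def segment_beats(
    beat_times: np.ndarray, duration: float, epoch_length: float = EPOCH_SECONDS
) -> list[np.ndarray]:
    """Assign beat times to half-open epochs ``[i*L, (i+1)*L)``.

    ``duration`` is the recording length in seconds; the number of epochs
    is ``floor(duration / epoch_length)`` and trailing beats are dropped.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    n_epochs = int(duration // epoch_length)
    if n_epochs == 0:
        logger.warning("recording shorter than one epoch (%.1f s)", duration)
        return []
    idx = np.floor(beat_times / epoch_length).astype(int)
    return [beat_times[idx == i] for i in range(n_epochs)]


def min_beats_filter(beats_in_epoch: np.ndarray) -> bool:
    """Keep an epoch only if it contains at least 15 detected beats."""
    return np.asarray(beats_in_epoch).size >= MIN_BEATS


def adjust_border_beats(beat_times: np.ndarray) -> tuple[np.ndarray, bool]:
    """Re-anchor the first and last beat of an epoch by extrapolation.

    The first beat time becomes the second beat time minus the mean of the
    second and third beat intervals; the last becomes the second-last beat
    time plus the mean of the second-last and third-last intervals. This
    removes border gaps that would distort the 4 Hz interpolation. With
    fewer than 4 beats the input is returned unmodified (flagged False).
    """
    t = np.asarray(beat_times, dtype=float)
    if t.size < 4:
        return t, False
    d = np.diff(t)
    out = t.copy()
    out[0] = t[1] - 0.5 * (d[1] + d[2])
    out[-1] = t[-2] + 0.5 * (d[-2] + d[-3])
    if np.any(np.diff(out) <= 0):
        raise ValueError("border adjustment produced non-increasing beat times")
    return out, True


def beats_to_hr(beat_times: np.ndarray) -> np.ndarray:
    """Instantaneous heart rate per beat interval, HR = 60/R-R (BPM)."""
    t = np.asarray(beat_times, dtype=float)
    rr = np.diff(t)
    if np.any(rr <= 0):
        raise ValueError("beat times must be strictly increasing")
    return 60.0 / rr


def detect_hr_outliers(hr_segment: np.ndarray) -> np.ndarray:
    """Flag tachogram samples violating any of the three outlier rules.

    A sample is an outlier when it lies outside 40-180 BPM, outside the
    segment's median +/- 20 BPM, or outside the segment's median +/- 3 SD
    (median and SD of the raw segment). The mask is the union of the three.
    """
    x = np.asarray(hr_segment, dtype=float)
    med = np.median(x)
    sd = np.std(x)
    return (
        (x < HR_RANGE[0])
        | (x > HR_RANGE[1])
        | (np.abs(x - med) > HR_MEDIAN_BAND)
        | (np.abs(x - med) > HR_SD_FACTOR * sd)
    )


def _mask_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as (start, length)."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    return [(int(s), int(e - s + 1)) for s, e in zip(starts, ends)]


def correct_or_reject(
    segment: np.ndarray,
    mask: np.ndarray,
    max_gap: float = MAX_GAP_SECONDS,
) -> tuple[np.ndarray | None, str]:
    """Mirror-fill short outlier runs; reject the segment on long ones.

    Each maximal outlier run of length ``L <= max_gap * 4 Hz`` samples is
    replaced by the ``L`` samples immediately preceding it in reversed
    order. A run at the very start of the segment (no preceding samples)
    is filled by mirroring the samples that follow it instead. Any run
    longer than ``max_gap`` rejects the whole segment.

    Returns ``(corrected, "")`` or ``(None, reason)``.
    """
    x = np.asarray(segment, dtype=float).copy()
    mask = np.asarray(mask, dtype=bool)
    max_run = int(round(max_gap * EPOCH_GRID_HZ))
    for start, length in _mask_runs(mask):
        if length > max_run:
            return None, REASON_LONG_OUTLIER
        if start >= length:
            x[start : start + length] = x[start - length : start][::-1]
        elif start + 2 * length <= x.size:
            # no preceding samples: mirror the following ones instead
            logger.debug("outlier run at segment start; mirrored following samples")
            x[start : start + length] = x[start + length : start + 2 * length][::-1]
        else:
            return None, REASON_LONG_OUTLIER
    return x, ""


def _epoch_grid(epoch_index: int) -> np.ndarray:
    return epoch_index * EPOCH_SECONDS + np.arange(EPOCH_SAMPLES) / EPOCH_GRID_HZ


def build_tachogram(
    beats_in_epoch: np.ndarray,
    epoch_index: int,
    stats: PatientStats,
) -> TachogramSegment:
    """Full cardiac chain for one epoch's beats.

    Applies the minimum-beat filter, border-beat adjustment, HR
    extraction, 4 Hz linear interpolation (each interval's HR anchored at
    the beat closing it), outlier detection and mirror correction, and the
    patient-median subtraction.
    """
    beats = np.asarray(beats_in_epoch, dtype=float)
    if not min_beats_filter(beats):
        return TachogramSegment(epoch_index, None, rejected=True, reason=REASON_MIN_BEATS)
    beats, _ = adjust_border_beats(beats)
    hr = beats_to_hr(beats)
    grid = _epoch_grid(epoch_index)
    tach = np.interp(grid, beats[1:], hr)
    mask = detect_hr_outliers(tach)
    corrected, reason = correct_or_reject(tach, mask)
    if corrected is None:
        return TachogramSegment(epoch_index, None, rejected=True, reason=reason)
    return TachogramSegment(epoch_index, corrected - stats.median_hr)


def filter_respiration(resp_signal: np.ndarray, resp_fs: float) -> np.ndarray:
    """Band-pass the effort signal to 0.04-2 Hz (order-4 Butterworth).

    Applied forward-backward (zero-phase) so epochs stay aligned to the
    hypnogram. ``resp_fs`` must exceed 4 Hz so the 2 Hz edge is below
    Nyquist.
    """
    if resp_fs <= 2 * BAND_HZ[1]:
        raise ValueError(f"resp_fs must exceed {2 * BAND_HZ[1]} Hz, got {resp_fs}")
    sos = sps.butter(FILTER_ORDER, BAND_HZ, btype="bandpass", fs=resp_fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(resp_signal, dtype=float))


def resample_4hz(x: np.ndarray, fs: float) -> np.ndarray:
    """Polyphase-resample a signal to the 4 Hz epoch grid (anti-aliased)."""
    if fs == EPOCH_GRID_HZ:
        return np.asarray(x, dtype=float)
    frac = Fraction(EPOCH_GRID_HZ / fs).limit_denominator(1000)
    return sps.resample_poly(np.asarray(x, dtype=float), frac.numerator, frac.denominator)


def normalize_sd(epoch_values: np.ndarray, stats: PatientStats, epoch_index: int = 0) -> RespSegment:
    """Patient-level z-like scheme: (x - patient median)/patient SD, then
    subtract the segment's own median (so every output has median 0)."""
    if stats.sd_resp <= 0:
        raise ValueError("degenerate recording: respiratory SD is zero")
    x = (np.asarray(epoch_values, dtype=float) - stats.median_resp) / stats.sd_resp
    x = x - np.median(x)
    return RespSegment(epoch_index, x, scheme="sd")


def normalize_minmax(epoch_values: np.ndarray, epoch_index: int = 0) -> RespSegment:
    """Scale one segment to the range [-0.5, 0.5].

    Unlike the sd scheme this is invariant to positive affine transforms
    of the input, which removes the amplitude cue between sensors. A
    constant segment maps to all zeros (flagged).
    """
    x = np.asarray(epoch_values, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return RespSegment(epoch_index, np.zeros_like(x), scheme="minmax", constant_input=True)
    return RespSegment(epoch_index, (x - lo) / (hi - lo) - 0.5, scheme="minmax")


def quality_gate(
    retained: np.ndarray,
    quality_flags: np.ndarray,
    mode: str = "full",
) -> np.ndarray:
    """Combine rejection bookkeeping with the quality policy.

    ``retained`` marks epochs that survived preprocessing; ``quality_flags``
    is the per-epoch high-quality mask. ``mode="clean"`` keeps only
    high-quality retained epochs, ``mode="full"`` keeps all retained
    epochs. Returns the boolean mask of kept epochs (the denominator
    bookkeeping stays with the caller via ``retained``).
    """
    retained = np.asarray(retained, dtype=bool)
    if mode == "full":
        return retained.copy()
    if mode == "clean":
        return retained & np.asarray(quality_flags, dtype=bool)
    raise ValueError(f"mode must be 'full' or 'clean', got {mode!r}")


def compute_patient_stats(
    beat_times: np.ndarray, resp_filtered: np.ndarray
) -> PatientStats:
    """Whole-recording median HR and respiratory median/SD.

    Computed before any epoch rejection so rejected epochs cannot shift
    the normalization. ``resp_filtered`` is the band-passed signal.
    """
    hr = beats_to_hr(beat_times) if np.asarray(beat_times).size >= 2 else np.array([np.nan])
    resp = np.asarray(resp_filtered, dtype=float)
    return PatientStats(
        median_hr=float(np.median(hr)),
        median_resp=float(np.median(resp)),
        sd_resp=float(np.std(resp)),
    )


@dataclass
class EpochData:
    """Preprocessed CNN inputs for one recording.

    Arrays are aligned over *all* epochs; ``retained_*`` mark the epochs
    whose vectors are valid. ``X_card`` rows of rejected epochs are zero.
    """

    patient_id: str
    stage: np.ndarray  # ground-truth hypnogram, all epochs
    X_resp: np.ndarray  # (n_epochs, 120)
    X_card: np.ndarray  # (n_epochs, 120)
    retained_resp: np.ndarray  # bool
    retained_card: np.ndarray  # bool
    card_reason: list[str]
    quality_resp: np.ndarray  # bool, True = high
    quality_card: np.ndarray
    ahi: float
    group: str

    @property
    def n_epochs(self) -> int:
        return int(self.stage.size)


def preprocess_recording(
    recording: PatientRecording,
    norm: str = "minmax",
) -> EpochData:
    """Run both preprocessing chains over a whole recording.

    ``norm`` selects the respiratory scheme ("minmax" or "sd"). Cardiac
    epochs rejected by the minimum-beat or long-outlier rule are marked in
    ``retained_card`` with their reason.
    """
    if norm not in ("minmax", "sd"):
        raise ValueError(f"norm must be 'minmax' or 'sd', got {norm!r}")
    n_epochs = recording.n_epochs

    filtered = filter_respiration(recording.resp_signal, recording.resp_fs)
    stats = compute_patient_stats(recording.beat_times, filtered)
    resp4 = resample_4hz(filtered, recording.resp_fs)
    resp_epochs = segment_signal(resp4, EPOCH_GRID_HZ)[:n_epochs]

    X_resp = np.zeros((n_epochs, EPOCH_SAMPLES))
    retained_resp = np.zeros(n_epochs, dtype=bool)
    for i in range(min(len(resp_epochs), n_epochs)):
        if norm == "minmax":
            seg = normalize_minmax(resp_epochs[i], i)
        else:
            seg = normalize_sd(resp_epochs[i], stats, i)
        X_resp[i] = seg.values
        retained_resp[i] = True

    beats_per_epoch = segment_beats(recording.beat_times, recording.duration)
    X_card = np.zeros((n_epochs, EPOCH_SAMPLES))
    retained_card = np.zeros(n_epochs, dtype=bool)
    card_reason = [""] * n_epochs
    for i, beats in enumerate(beats_per_epoch):
        tach = build_tachogram(beats, i, stats)
        if tach.rejected:
            card_reason[i] = tach.reason
        else:
            X_card[i] = tach.values
            retained_card[i] = True

    quality = recording.quality or {}
    ones = np.ones(n_epochs, dtype=bool)
    return EpochData(
        patient_id=recording.patient_id,
        stage=recording.hypnogram.copy(),
        X_resp=X_resp,
        X_card=X_card,
        retained_resp=retained_resp,
        retained_card=retained_card,
        card_reason=card_reason,
        quality_resp=np.asarray(quality.get("resp", ones), dtype=bool),
        quality_card=np.asarray(quality.get("cardiac", ones), dtype=bool),
        ahi=recording.ahi,
        group=recording.group,
    )
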