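"""Domain types shared across the pipeline.

Conventions used everywhere in the package:

* an *epoch* is a 30 s scoring window; epoch ``i`` covers the half-open
  interval ``[30*i, 30*(i+1))`` seconds from recording start (0-based);
* hypnograms are binary integer arrays with ``SLEEP == 0`` and ``WAKE == 1``;
* times are seconds from recording start, heart rate is in beats per minute
  (BPM), the apnea-hypopnea index (AHI) is respiratory events per hour of
  sleep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

EPOCH_SECONDS: float = 30.0
#: CNN input grid: 30 s epochs sampled at 4 Hz.
EPOCH_GRID_HZ: float = 4.0
EPOCH_SAMPLES: int = int(EPOCH_SECONDS * EPOCH_GRID_HZ)  # 120

SLEEP: int = 0
WAKE: int = 1

#: AHI severity classes (events/h): half-open [lo, hi) except Sev which is
#: closed at the simulation cap of 100/h.
GROUP_AHI_BOUNDS: dict[str, tuple[float, float]] = {
    "No": (0.0, 5.0),
    "Mild": (5.0, 15.0),
    "Mod": (15.0, 30.0),
    "Sev": (30.0, 100.0),
}

OBSTRUCTIVE_APNEA = "obstructive_apnea"
OBSTRUCTIVE_HYPOPNEA = "obstructive_hypopnea"

QUALITY_HIGH = "high"
QUALITY_LOW = "low"


def group_for_ahi(ahi: float) -> str:
    """Severity class label for an AHI value (events/h)."""
    if ahi < 0:
        raise ValueError(f"AHI must be non-negative, got {ahi}")
    if ahi < 5:
        return "No"
    if ahi < 15:
        return "Mild"
    if ahi < 30:
        return "Mod"
    return "Sev"


@dataclass(frozen=True)
class ApneaEvent:
    """A single obstructive respiratory event."""

    onset: float  # seconds from recording start
    duration: float  # seconds
    kind: str  # OBSTRUCTIVE_APNEA or OBSTRUCTIVE_HYPOPNEA

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class CohortSpec:
    """Composition and global settings of a synthetic cohort.

    ``n_per_group`` maps severity class to patient count; the default is the
    36-patient test composition 6/4/9/17 (No/Mild/Mod/Sev).
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"No": 6, "Mild": 4, "Mod": 9, "Sev": 17}
    )
    recording_hours: float = 8.0
    epoch_length: float = EPOCH_SECONDS
    wake_fraction_range: tuple[float, float] = (0.14, 0.27)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epoch_length != EPOCH_SECONDS:
            raise ValueError("epoch_length is fixed at 30 s")
        duration = self.recording_hours * 3600.0
        if duration <= 0 or duration % self.epoch_length:
            raise ValueError("epoch_length must divide the recording duration")
        lo, hi = self.wake_fraction_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("wake_fraction_range must lie within (0, 1)")
        unknown = set(self.n_per_group) - set(GROUP_AHI_BOUNDS)
        if unknown:
            raise ValueError(f"unknown severity groups: {sorted(unknown)}")
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("group counts must be non-negative")

    @property
    def n_epochs(self) -> int:
        return int(self.recording_hours * 3600.0 / self.epoch_length)

    @property
    def n_patients(self) -> int:
        return sum(self.n_per_group.values())


@dataclass
class ArtifactModel:
    """Movement-artifact and quality-degradation model for the generator.

    Motion bursts are large transients superimposed on the effort signal;
    they occur at a higher rate in wake than in sleep and, with probability
    ``post_apnea_burst_prob``, at the restoration of breathing that
    terminates an apnea. An epoch is graded low quality when the energy of
    the artifact component injected into it exceeds
    ``quality_energy_threshold``.
    """

    motion_burst_rate_wake: float = 80.0  # bursts/hour while awake
    motion_burst_rate_sleep: float = 5.0  # bursts/hour while asleep
    post_apnea_burst_prob: float = 0.35
    burst_amplitude_factor: float = 6.0  # burst amplitude / baseline amplitude
    drift_amplitude: float = 0.05  # slow baseline wander, baseline units
    quality_energy_threshold: float = 5.0  # (signal units)^2 * s per epoch
    #: cardiac channel picks up the same body movement with higher gain
    cardiac_energy_gain: float = 2.0

    def __post_init__(self) -> None:
        if self.motion_burst_rate_wake < self.motion_burst_rate_sleep or (
            self.motion_burst_rate_wake == self.motion_burst_rate_sleep
            and self.motion_burst_rate_wake > 0
        ):
            # movement is more frequent awake; the all-zero (artifact-free)
            # degenerate model is allowed
            raise ValueError("wake burst rate must exceed sleep burst rate")
        if not 0.0 <= self.post_apnea_burst_prob <= 1.0:
            raise ValueError("post_apnea_burst_prob must be in [0, 1]")


@dataclass
class PatientRecording:
    """One synthetic (or imported) night of cardiorespiratory data."""

    patient_id: str
    beat_times: np.ndarray  # seconds, strictly increasing
    resp_signal: np.ndarray
    resp_fs: float  # Hz
    hypnogram: np.ndarray  # per-epoch int8, SLEEP/WAKE
    events: list[ApneaEvent]
    quality: dict[str, np.ndarray]  # modality -> per-epoch bool, True = high
    ahi: float
    group: str = ""

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.resp_signal = np.asarray(self.resp_signal, dtype=float)
        self.hypnogram = np.asarray(self.hypnogram, dtype=np.int8)
        if not self.group:
            self.group = group_for_ahi(self.ahi)

    @property
    def n_epochs(self) -> int:
        return int(self.hypnogram.size)

    @property
    def duration(self) -> float:
        return self.n_epochs * EPOCH_SECONDS

    @property
    def sleep_hours(self) -> float:
        return float(np.sum(self.hypnogram == SLEEP)) * EPOCH_SECONDS / 3600.0

    def apnea_epoch_mask(self) -> np.ndarray:
        """Boolean mask of epochs overlapping any respiratory event."""
        mask = np.zeros(self.n_epochs, dtype=bool)
        for ev in self.events:
            first = int(ev.onset // EPOCH_SECONDS)
            # epoch containing the last covered instant
            last = int(np.ceil(ev.end / EPOCH_SECONDS)) - 1
            mask[max(first, 0) : min(last, self.n_epochs - 1) + 1] = True
        return mask


@dataclass
class PredictionSeries:
    """Per-epoch sleep-wake prediction for one recording.

    Only retained (non-rejected) epochs carry rows; ``epoch_index`` keeps
    the original position so indices can be computed in temporal order.
    """

    epoch_index: np.ndarray  # int
    p_wake: np.ndarray
    p_sleep: np.ndarray
    label: np.ndarray  # SLEEP/WAKE, argmax with p_wake == 0.5 -> SLEEP
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.epoch_index = np.asarray(self.epoch_index, dtype=int)
        self.p_wake = np.asarray(self.p_wake, dtype=float)
        self.p_sleep = np.asarray(self.p_sleep, dtype=float)
        self.label = np.asarray(self.label, dtype=np.int8)
        if not (
            self.epoch_index.size == self.p_wake.size == self.p_sleep.size == self.label.size
        ):
            raise ValueError("prediction columns must have equal length")

    def __len__(self) -> int:
        return int(self.epoch_index.size)

    @classmethod
    def from_probabilities(
        cls, epoch_index: Sequence[int], p_wake: Sequence[float], patient_id: str = ""
    ) -> "PredictionSeries":
        p_wake = np.asarray(p_wake, dtype=float)
        label = np.where(p_wake > 0.5, WAKE, SLEEP)  # tie -> sleep (majority class)
        return cls(
            epoch_index=np.asarray(epoch_index, dtype=int),
            p_wake=p_wake,
            p_sleep=1.0 - p_wake,
            label=label,
            patient_id=patient_id,
        )


@dataclass(frozen=True)
class ConfidenceThresholds:
    """Confidence cut-offs on the predicted-class probability.

    Each threshold is the median minus the SD of the pooled predicted-class
    probability over a reference cohort: a sleep-predicted epoch is
    *confident* when ``p_sleep >= t_sleep`` (likewise for wake).
    """

    t_sleep: float
    t_wake: float

    def __post_init__(self) -> None:
        for name, t in (("t_sleep", self.t_sleep), ("t_wake", self.t_wake)):
            if not 0.0 < t < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {t}")


@dataclass(frozen=True)
class IndexThresholds:
    """Operating points of the bivariate patient-detection model (percent)."""

    thr_uncertain: float = 66.0
    thr_transitions: float = 24.3
    target_specificity: float = 0.92

    def __post_init__(self) -> None:
        for name, t in (
            ("thr_uncertain", self.thr_uncertain),
            ("thr_transitions", self.thr_transitions),
        ):
            if not 0.0 <= t <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100], got {t}")


@dataclass
class RiskProfile:
    """Per-patient detection indices and the either-index risk decision."""

    patient_id: str
    pct_uncertain_sleep: float
    pct_transitions: float
    at_risk: bool
    no_sleep_predictions: bool = False  # flagged when the first index had an empty denominator


@dataclass
class DetectionMetrics:
    """Agreement metrics of a binary screening decision against truth.

    ``se``/``sp``/``acc`` are percentages; ``dor`` is the diagnostic odds
    ratio Se*Sp / ((1-Se)(1-Sp)) on fractions. ``dor_corrected`` marks a
    Haldane-Anscombe 0.5-count correction applied because of a zero cell
    (``dor`` is NaN when truth or decisions are degenerate).
    """

    kappa: float
    acc: float
    se: float
    sp: float
    dor: float
    tp: int
    fp: int
    fn: int
    tn: int
    dor_corrected: bool = False
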