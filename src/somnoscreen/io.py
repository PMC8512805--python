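"""CSV sidecar formats and recording (de)serialization.

Per-patient on-disk layout (all epochs 0-based, half-open [30i, 30(i+1))
seconds): an EDF with the respiratory channel plus CSV sidecars for the
hypnogram, the apnea events, the beat times and the per-epoch quality
flags, and a cohort-level metadata CSV (patient_id, ahi, group).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from somnoscreen import edf
from somnoscreen.types import (
    ApneaEvent,
    PatientRecording,
    PredictionSeries,
    QUALITY_HIGH,
    QUALITY_LOW,
    RiskProfile,
    SLEEP,
    WAKE,
)

__all__ = [
    "stage_to_binary",
    "read_hypnogram_csv",
    "write_recording",
    "read_recording",
    "write_cohort",
    "read_cohort",
    "write_predictions_csv",
    "read_predictions_csv",
    "write_risk_report",
    "write_scatter_export",
]

RESP_CHANNEL = "Resp effort"

#: collapse rule for multi-stage hypnogram vocabularies
_STAGE_VOCAB = {
    "W": WAKE, "WAKE": WAKE,
    "N1": SLEEP, "N2": SLEEP, "N3": SLEEP, "N4": SLEEP,
    "S": SLEEP, "SLEEP": SLEEP, "REM": SLEEP, "R": SLEEP,
}


def stage_to_binary(stage: str) -> int:
    try:
        return _STAGE_VOCAB[str(stage).strip().upper()]
    except KeyError:
        raise ValueError(f"unknown sleep stage label: {stage!r}") from None


def read_hypnogram_csv(path: str | Path) -> np.ndarray:
    """Load a per-epoch hypnogram; multi-stage vocabularies collapse to
    binary (W -> wake, everything else -> sleep).

    Validates that epoch indices are 0..n-1 without gaps or duplicates.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty hypnogram")
    if not {"epoch_index", "stage"} <= set(df.columns):
        raise ValueError(f"{path}: need columns epoch_index,stage")
    idx = df["epoch_index"].to_numpy()
    expected = np.arange(len(df))
    if not np.array_equal(np.sort(idx), expected):
        raise ValueError(f"{path}: epoch_index must be 0..{len(df) - 1} without gaps/duplicates")
    df = df.sort_values("epoch_index")
    return np.array([stage_to_binary(s) for s in df["stage"]], dtype=np.int8)


def _stage_name(v: int) -> str:
    return "wake" if v == WAKE else "sleep"


def write_recording(rec: PatientRecording, out_dir: str | Path) -> Path:
    """Write one recording as EDF + CSV sidecars under ``out_dir/<id>/``."""
    d = Path(out_dir) / rec.patient_id
    d.mkdir(parents=True, exist_ok=True)
    edf.write_edf(d / "resp.edf", [(RESP_CHANNEL, rec.resp_signal, rec.resp_fs)], rec.patient_id)
    pd.DataFrame(
        {"epoch_index": np.arange(rec.n_epochs), "stage": [_stage_name(s) for s in rec.hypnogram]}
    ).to_csv(d / "hypnogram.csv", index=False)
    pd.DataFrame(
        {
            "onset_s": [e.onset for e in rec.events],
            "duration_s": [e.duration for e in rec.events],
            "type": [e.kind for e in rec.events],
        }
    ).to_csv(d / "events.csv", index=False)
    pd.DataFrame({"time_s": rec.beat_times}).to_csv(d / "beats.csv", index=False)
    rows = []
    for modality, flags in rec.quality.items():
        for i, high in enumerate(flags):
            rows.append((i, modality, QUALITY_HIGH if high else QUALITY_LOW))
    pd.DataFrame(rows, columns=["epoch_index", "modality", "flag"]).to_csv(
        d / "quality.csv", index=False
    )
    return d


def read_recording(patient_dir: str | Path, ahi: float, group: str = "") -> PatientRecording:
    """Load a recording written by :func:`write_recording`."""
    d = Path(patient_dir)
    sig, fs = edf.read_edf(d / "resp.edf", [RESP_CHANNEL])[RESP_CHANNEL]
    hyp = read_hypnogram_csv(d / "hypnogram.csv")
    ev = pd.read_csv(d / "events.csv")
    events = [
        ApneaEvent(onset=float(r.onset_s), duration=float(r.duration_s), kind=str(r.type))
        for r in ev.itertuples()
    ]
    beats = pd.read_csv(d / "beats.csv")["time_s"].to_numpy(dtype=float)
    q = pd.read_csv(d / "quality.csv")
    quality = {}
    for modality, grp in q.groupby("modality"):
        flags = np.ones(hyp.size, dtype=bool)
        flags[grp["epoch_index"].to_numpy()] = grp["flag"].to_numpy() == QUALITY_HIGH
        quality[str(modality)] = flags
    return PatientRecording(
        patient_id=d.name,
        beat_times=beats,
        resp_signal=sig,
        resp_fs=fs,
        hypnogram=hyp,
        events=events,
        quality=quality,
        ahi=ahi,
        group=group,
    )


def write_cohort(cohort: list[PatientRecording], out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in cohort:
        write_recording(rec, out_dir)
    pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in cohort],
            "ahi": [r.ahi for r in cohort],
            "group": [r.group for r in cohort],
        }
    ).to_csv(out_dir / "meta.csv", index=False)
    return out_dir


def read_cohort(in_dir: str | Path) -> list[PatientRecording]:
    in_dir = Path(in_dir)
    meta = pd.read_csv(in_dir / "meta.csv")
    return [
        read_recording(in_dir / str(r.patient_id), float(r.ahi), str(r.group))
        for r in meta.itertuples()
    ]


def write_predictions_csv(series: list[PredictionSeries], path: str | Path) -> Path:
    frames = [
        pd.DataFrame(
            {
                "patient_id": s.patient_id,
                "epoch_index": s.epoch_index,
                "p_wake": s.p_wake,
                "p_sleep": s.p_sleep,
                "label": [_stage_name(v) for v in s.label],
            }
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return Path(path)


def read_predictions_csv(path: str | Path) -> list[PredictionSeries]:
    df = pd.read_csv(path)
    out = []
    for pid, grp in df.groupby("patient_id", sort=False):
        out.append(
            PredictionSeries(
                epoch_index=grp["epoch_index"].to_numpy(),
                p_wake=grp["p_wake"].to_numpy(),
                p_sleep=grp["p_sleep"].to_numpy(),
                label=np.where(grp["label"].to_numpy() == "wake", WAKE, SLEEP),
                patient_id=str(pid),
            )
        )
    return out


def write_risk_report(profiles: list[RiskProfile], path: str | Path) -> Path:
    pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in profiles],
            "pct_uncertain_sleep": [p.pct_uncertain_sleep for p in profiles],
            "pct_transitions": [p.pct_transitions for p in profiles],
            "decision": ["at-risk" if p.at_risk else "not-at-risk" for p in profiles],
        }
    ).to_csv(path, index=False)
    return Path(path)


def write_scatter_export(
    profiles: list[RiskProfile],
    truth: dict[str, bool],
    thr_uncertain: float,
    thr_transitions: float,
    path: str | Path,
) -> Path:
    """Bivariate index scatter (one row per patient + the threshold lines),
    the geometry of the risk plane: at-risk is the region where either
    coordinate exceeds its threshold line."""
    df = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in profiles],
            "pct_uncertain_sleep": [p.pct_uncertain_sleep for p in profiles],
            "pct_transitions": [p.pct_transitions for p in profiles],
            "truth_positive": [truth.get(p.patient_id, False) for p in profiles],
            "thr_uncertain": thr_uncertain,
            "thr_transitions": thr_transitions,
        }
    )
    df.to_csv(path, index=False)
    return Path(path)
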