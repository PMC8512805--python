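"""End-to-end experiment orchestration.

``run_pipeline`` executes the full chain -- synthesize cohorts,
preprocess, train/select the classifier, predict, derive risk indices,
evaluate detection -- under one root seed, writing every stage's outputs
plus a manifest of content hashes so a rerun with the same configuration
is reproducible (and, with ``resume=True``, skips completed stages whose
configuration hash matches).

Randomness flows from ``config.seed`` through named per-stage substreams,
so each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from somnoscreen import io as sio
from somnoscreen import osa_risk, preprocess, sleepwake, synthgen
from somnoscreen.preprocess import EpochData
from somnoscreen.types import CohortSpec, IndexThresholds

__all__ = ["PipelineConfig", "run_pipeline", "save_model", "load_model", "save_epoch_data", "load_epoch_data"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration of one experiment run.

    Round-trips losslessly through YAML; every run writes the resolved
    config beside its outputs.
    """

    seed: int = 0
    # cohorts
    n_per_group: dict = field(default_factory=lambda: {"No": 6, "Mild": 4, "Mod": 9, "Sev": 17})
    recording_hours: float = 8.0
    wake_fraction_range: tuple = (0.14, 0.27)
    train_pool_patients: int = 20
    selection_patients: int = 8
    # preprocessing
    norm: str = "minmax"
    mode: str = "full"
    # network and training
    branches: tuple = ("respiratory",)
    augment: bool = True
    n_repeats: int = 10
    max_passes: int = 40
    batch_size: int = 64
    patience: int = 10
    # risk model
    target_specificity: float = 0.92
    truth_cuts: tuple = (15.0, 30.0)

    def to_yaml(self, path: str | Path) -> Path:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return Path(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("wake_fraction_range", "branches", "truth_cuts"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        if "n_per_group" in raw:
            # YAML 1.1 reads a bare `No` key as boolean False
            raw["n_per_group"] = {
                ("No" if k is False else str(k)): v for k, v in raw["n_per_group"].items()
            }
        return cls(**raw)

    def stage_hash(self, stage: str) -> str:
        payload = json.dumps({"stage": stage, **dataclasses.asdict(self)}, sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data = json.loads(path.read_text()) if path.exists() else {}

    def done(self, stage: str, config_hash: str) -> bool:
        entry = self.data.get(stage)
        if not entry or entry["config_hash"] != config_hash:
            return False
        return all(Path(p).exists() for p in entry["outputs"])

    def record(self, stage: str, config_hash: str, outputs: list[Path], warnings: list[str] = ()) -> None:
        self.data[stage] = {
            "config_hash": config_hash,
            "outputs": {str(p): _sha256(p) for p in outputs},
            "warnings": list(warnings),
        }
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


# -- serialization helpers -------------------------------------------------

def save_epoch_data(data: EpochData, path: str | Path) -> Path:
    np.savez_compressed(
        path,
        stage=data.stage,
        X_resp=data.X_resp,
        X_card=data.X_card,
        retained_resp=data.retained_resp,
        retained_card=data.retained_card,
        card_reason=np.array(data.card_reason),
        quality_resp=data.quality_resp,
        quality_card=data.quality_card,
        ahi=data.ahi,
        group=data.group,
        patient_id=data.patient_id,
    )
    return Path(path)


def load_epoch_data(path: str | Path) -> EpochData:
    z = np.load(path, allow_pickle=False)
    return EpochData(
        patient_id=str(z["patient_id"]),
        stage=z["stage"],
        X_resp=z["X_resp"],
        X_card=z["X_card"],
        retained_resp=z["retained_resp"],
        retained_card=z["retained_card"],
        card_reason=[str(r) for r in z["card_reason"]],
        quality_resp=z["quality_resp"],
        quality_card=z["quality_card"],
        ahi=float(z["ahi"]),
        group=str(z["group"]),
    )


def save_model(model: sleepwake.SleepWakeNet, path: str | Path) -> Path:
    """Checkpoint: parameter arrays plus a plain-text config snapshot."""
    path = Path(path)
    np.savez(path, **{f"param_{i}": p for i, p in enumerate(model.all_params())})
    snap = path.with_suffix(".config.yaml")
    snap.write_text(yaml.safe_dump(dataclasses.asdict(model.config)))
    return path


def load_model(path: str | Path) -> sleepwake.SleepWakeNet:
    path = Path(path)
    raw = yaml.safe_load(path.with_suffix(".config.yaml").read_text())
    for key in ("branches", "conv_filters"):
        raw[key] = tuple(raw[key])
    model = sleepwake.SleepWakeNet(sleepwake.NetworkConfig(**raw))
    z = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    model.load_state([z[f"param_{i}"] for i in range(len(model.all_params()))])
    return model


# -- pipeline --------------------------------------------------------------

def _preprocess_cohort(cohort, norm: str) -> list[EpochData]:
    return [preprocess.preprocess_recording(rec, norm=norm) for rec in cohort]


def run_pipeline(config: PipelineConfig, out_dir: str | Path, resume: bool = False) -> dict:
    """Execute synth -> preprocess -> train -> predict -> risk -> evaluate.

    Returns a result dict with the selection table, fitted thresholds and
    per-cut detection metrics; all artifacts land under ``out_dir``.
    """
    if sum(config.n_per_group.values()) == 0:
        raise ValueError("test cohort is empty: n_per_group sums to zero")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest = _Manifest(out / "manifest.json")

    # stage: synth ---------------------------------------------------------
    synth_dir = out / "synth"
    h = config.stage_hash("synth")
    spec = CohortSpec(
        n_per_group=dict(config.n_per_group),
        recording_hours=config.recording_hours,
        wake_fraction_range=tuple(config.wake_fraction_range),
        seed=config.seed,
    )
    if resume and manifest.done("synth", h):
        logger.info("synth: resumed (hash match)")
    else:
        pool = synthgen.generate_low_ahi_cohort(
            config.train_pool_patients, seed=config.seed, recording_hours=config.recording_hours
        )
        selection = synthgen.generate_low_ahi_cohort(
            config.selection_patients, seed=config.seed + 101, recording_hours=config.recording_hours
        )
        for i, rec in enumerate(selection):
            rec.patient_id = f"S{i:03d}"
        tune = synthgen.generate_cohort(dataclasses.replace(spec, seed=config.seed + 202))
        for rec in tune:
            rec.patient_id = "U" + rec.patient_id
        test = synthgen.generate_cohort(spec)
        outputs = []
        for name, cohort in [("pool", pool), ("selection", selection), ("tune", tune), ("test", test)]:
            outputs.append(sio.write_cohort(cohort, synth_dir / name) / "meta.csv")
        manifest.record("synth", h, outputs)

    cohorts = {name: sio.read_cohort(synth_dir / name) for name in ("pool", "selection", "tune", "test")}

    # stage: preprocess ----------------------------------------------------
    pre_dir = out / "preprocess"
    h = config.stage_hash("preprocess")
    if resume and manifest.done("preprocess", h):
        logger.info("preprocess: resumed (hash match)")
    else:
        outputs = []
        for name, cohort in cohorts.items():
            d = pre_dir / name
            d.mkdir(parents=True, exist_ok=True)
            rows = []
            for rec in cohort:
                ed = preprocess.preprocess_recording(rec, norm=config.norm)
                outputs.append(save_epoch_data(ed, d / f"{rec.patient_id}.npz"))
                for i in range(ed.n_epochs):
                    rows.append(
                        (rec.patient_id, i, bool(ed.retained_card[i]), ed.card_reason[i],
                         "high" if ed.quality_resp[i] else "low")
                    )
            import pandas as pd

            pd.DataFrame(
                rows, columns=["patient_id", "epoch_index", "cardiac_kept", "reason", "resp_quality"]
            ).to_csv(d / "manifest.csv", index=False)
            outputs.append(d / "manifest.csv")
        manifest.record("preprocess", h, outputs)

    data = {
        name: [load_epoch_data(p) for p in sorted((pre_dir / name).glob("*.npz"))]
        for name in cohorts
    }

    # stage: train ---------------------------------------------------------
    h = config.stage_hash("train")
    model_path = out / "model.npz"
    if resume and manifest.done("train", h):
        model = load_model(model_path)
        table = json.loads((out / "selection_table.json").read_text())
        logger.info("train: resumed (hash match)")
    else:
        protocol = sleepwake.TrainingProtocol(n_repeats=config.n_repeats, seed_base=config.seed)
        net_config = sleepwake.NetworkConfig(branches=tuple(config.branches))
        aug = sleepwake.AugmentationConfig() if config.augment else None
        tc = sleepwake.TrainingConfig(
            batch_size=config.batch_size, max_passes=config.max_passes, patience=config.patience
        )
        model, table = sleepwake.repeated_training_select(
            data["pool"], data["selection"], protocol, net_config, aug, tc, mode=config.mode
        )
        save_model(model, model_path)
        (out / "selection_table.json").write_text(json.dumps(table, indent=2))
        manifest.record("train", h, [model_path, out / "selection_table.json"])

    # stage: predict -------------------------------------------------------
    h = config.stage_hash("predict")
    pred_paths = {}
    preds = {}
    for name in ("selection", "tune", "test"):
        preds[name] = [sleepwake.predict_recording(model, d, mode=config.mode) for d in data[name]]
        pred_paths[name] = sio.write_predictions_csv(preds[name], out / f"predictions_{name}.csv")
    manifest.record("predict", h, list(pred_paths.values()))

    # stage: risk ----------------------------------------------------------
    conf = osa_risk.fit_confidence_thresholds(preds["selection"])
    ahi_by_id = {d.patient_id: d.ahi for name in data for d in data[name]}

    def indices(series_list):
        unc, trans, ids = [], [], []
        for s in series_list:
            u, _ = osa_risk.pct_uncertain_sleep(s, conf)
            unc.append(u)
            trans.append(osa_risk.pct_transitions(s))
            ids.append(s.patient_id)
        return np.array(unc), np.array(trans), ids

    unc_t, trans_t, ids_t = indices(preds["tune"])
    truth_tune = np.array([ahi_by_id[i] >= 15.0 for i in ids_t])
    thr_unc, _, _ = osa_risk.roc_select_threshold(unc_t, truth_tune, config.target_specificity)
    thr_trans, _, _ = osa_risk.roc_select_threshold(trans_t, truth_tune, config.target_specificity)
    idx_thresholds = IndexThresholds(
        thr_uncertain=float(np.clip(thr_unc, 0, 100)),
        thr_transitions=float(np.clip(thr_trans, 0, 100)),
        target_specificity=config.target_specificity,
    )

    profiles = [osa_risk.risk_profile(s, conf, idx_thresholds) for s in preds["test"]]
    sio.write_risk_report(profiles, out / "risk_report.csv")
    truth15 = {p.patient_id: ahi_by_id[p.patient_id] >= 15.0 for p in profiles}
    sio.write_scatter_export(
        profiles, truth15, idx_thresholds.thr_uncertain, idx_thresholds.thr_transitions,
        out / "risk_scatter.csv",
    )

    # stage: evaluate ------------------------------------------------------
    decisions = np.array([p.at_risk for p in profiles])
    metrics = {}
    for cut in config.truth_cuts:
        truth = np.array([ahi_by_id[p.patient_id] >= cut for p in profiles])
        m = osa_risk.detection_metrics(decisions, truth)
        metrics[f"ahi_ge_{int(cut)}"] = dataclasses.asdict(m)
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    manifest.record("evaluate", config.stage_hash("evaluate"),
                    [out / "risk_report.csv", out / "risk_scatter.csv", out / "metrics.json"])

    return {
        "selection_table": table,
        "confidence_thresholds": conf,
        "index_thresholds": idx_thresholds,
        "profiles": profiles,
        "metrics": metrics,
    }
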