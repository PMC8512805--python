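"""Sleep-wake CNN classifiers: unimodal cardiac/respiratory and fused.

The classifier predicts wake vs sleep epoch-by-epoch from a single
120-sample (30 s at 4 Hz) input vector per modality: a
patient-median-subtracted tachogram and/or a normalized respiratory-effort
segment. Three elements matter for transfer to unobtrusive sensors:

* min-max input normalization, which removes the absolute-amplitude cue
  that does not transfer across sensor types,
* amplitude augmentation during training (each segment is rescaled with a
  fresh uniform factor in [0.2, 3.2] at every training step, with the
  dataset logically duplicated four times), which forces the network to
  rely on waveform shape and rate rather than amplitude,
* a repeated-training protocol: ten patient-level 70/30 train/validation
  resplits, keeping the network with the highest Cohen's kappa on a
  disjoint selection set.

A fused multimodal network combines the two trained convolutional stacks
under new dense layers; the convolutional weights are frozen and only the
head is retrained.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import cohen_kappa_score

from somnoscreen import nn
from somnoscreen.preprocess import EpochData, quality_gate
from somnoscreen.types import EPOCH_SAMPLES, PredictionSeries, SLEEP, WAKE

__all__ = [
    "NetworkConfig",
    "AugmentationConfig",
    "TrainingConfig",
    "TrainingProtocol",
    "SleepWakeNet",
    "Dataset",
    "build_network",
    "augment_batch",
    "train_network",
    "repeated_training_select",
    "fuse_multimodal",
    "predict",
    "predict_recording",
    "assemble_dataset",
    "pooled_kappa",
]

CARDIAC = "cardiac"
RESPIRATORY = "respiratory"


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture of a sleep-wake network.

    Defaults are a desk-scale three-block stack (8/16/32 filters, kernel 5,
    pool 2) per branch with a 32-unit dense head; ``branches`` selects the
    unimodal cardiac, unimodal respiratory, or two-branch multimodal form.
    """

    input_length: int = EPOCH_SAMPLES
    branches: tuple[str, ...] = (RESPIRATORY,)
    conv_filters: tuple[int, ...] = (8, 16, 32)
    kernel: int = 5
    pool: int = 2
    dense_units: int = 32
    dropout: float = 0.25
    n_classes: int = 2

    def __post_init__(self) -> None:
        if not self.branches or set(self.branches) - {CARDIAC, RESPIRATORY}:
            raise ValueError(f"branches must be a subset of (cardiac, respiratory), got {self.branches}")
        if self.n_classes != 2:
            raise ValueError("the sleep-wake task is two-class")


@dataclass(frozen=True)
class AugmentationConfig:
    """Amplitude augmentation: x4 logical duplication, random rescaling.

    ``apply_to`` limits the rescaling to specific branches (default: the
    respiratory branch only; the cardiac tachogram is in absolute BPM
    units and is not amplitude-confounded across sensors).
    """

    duplication_factor: int = 4
    scale_low: float = 0.2
    scale_high: float = 3.2
    per_step: bool = True
    apply_to: tuple[str, ...] = (RESPIRATORY,)

    def __post_init__(self) -> None:
        if not 0 < self.scale_low <= self.scale_high:
            raise ValueError("need 0 < scale_low <= scale_high")
        if self.duplication_factor < 1:
            raise ValueError("duplication_factor must be >= 1")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings (unremarkable defaults, fully configurable)."""

    lr: float = 1e-3
    batch_size: int = 64
    max_passes: int = 40
    patience: int = 10  # early stopping on validation loss


@dataclass(frozen=True)
class TrainingProtocol:
    """Repeated patient-level resplitting with kappa-based selection."""

    n_repeats: int = 10
    val_fraction: float = 0.3
    seed_base: int = 0
    ahi_cap: float = 10.0  # training-pool patients only


@dataclass
class Dataset:
    """Flat epoch matrix pooled over patients, with patient bookkeeping."""

    X: dict[str, np.ndarray]  # branch -> (n, 120)
    y: np.ndarray  # SLEEP/WAKE
    patient_ids: np.ndarray  # str per epoch
    epoch_index: np.ndarray

    def __len__(self) -> int:
        return int(self.y.size)

    def subset(self, mask: np.ndarray) -> "Dataset":
        return Dataset(
            {k: v[mask] for k, v in self.X.items()},
            self.y[mask],
            self.patient_ids[mask],
            self.epoch_index[mask],
        )


class SleepWakeNet:
    """One or two convolutional branches feeding a shared dense head."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.branches: dict[str, nn.Sequential] = {}
        feat_total = 0
        for name in config.branches:
            layers: list[nn.Layer] = []
            in_ch, length = 1, config.input_length
            for filters in config.conv_filters:
                layers += [nn.Conv1D(in_ch, filters, config.kernel, rng), nn.ReLU(), nn.MaxPool1D(config.pool)]
                length = (length - config.kernel + 1) // config.pool
                in_ch = filters
            layers.append(nn.Flatten())
            self.branches[name] = nn.Sequential(layers)
            feat_total += length * in_ch
        self._feat_sizes = {}
        off = 0
        for name in config.branches:
            size = feat_total // len(config.branches)  # branches are identical stacks
            self._feat_sizes[name] = (off, off + size)
            off += size
        self.head = nn.Sequential(
            [
                nn.Dense(feat_total, config.dense_units, rng),
                nn.ReLU(),
                nn.Dropout(config.dropout),
                nn.Dense(config.dense_units, config.n_classes, rng),
            ]
        )

    # -- forward/backward -------------------------------------------------
    def _branch_inputs(self, X: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        out = {}
        for name in self.config.branches:
            x = X[name]
            if x.shape[1] != self.config.input_length:
                raise ValueError(
                    f"{name} input length {x.shape[1]} != configured {self.config.input_length}"
                )
            out[name] = x[:, :, None] if x.ndim == 2 else x
        return out

    def forward(self, X: dict[str, np.ndarray], train: bool = False, rng=None) -> np.ndarray:
        xs = self._branch_inputs(X)
        feats = [self.branches[n].forward(xs[n], train=train, rng=rng) for n in self.config.branches]
        return self.head.forward(np.concatenate(feats, axis=1), train=train, rng=rng)

    def backward(self, dlogits: np.ndarray) -> None:
        dfeat = self.head.backward(dlogits)
        for name in self.config.branches:
            lo, hi = self._feat_sizes[name]
            self.branches[name].backward(dfeat[:, lo:hi])

    def params(self) -> list[np.ndarray]:
        out = []
        for name in self.config.branches:
            out += self.branches[name].params()
        return out + self.head.params()

    def grads(self) -> list[np.ndarray]:
        out = []
        for name in self.config.branches:
            out += self.branches[name].grads()
        return out + self.head.grads()

    # -- inference ---------------------------------------------------------
    def predict_proba(self, X: dict[str, np.ndarray], batch_size: int = 4096) -> np.ndarray:
        n = next(iter(X.values())).shape[0]
        out = np.empty((n, self.config.n_classes))
        for lo in range(0, n, batch_size):
            sl = slice(lo, lo + batch_size)
            out[sl] = nn.softmax(self.forward({k: v[sl] for k, v in X.items()}))
        return out

    def conv_checksum(self) -> float:
        """Checksum of all convolutional-branch weights (freeze contract)."""
        return float(sum(np.abs(p).sum() for b in self.branches.values() for p in b.all_params()))

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.all_params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.all_params(), state):
            p[...] = s

    def all_params(self) -> list[np.ndarray]:
        out = []
        for name in self.config.branches:
            out += self.branches[name].all_params()
        return out + self.head.all_params()


def build_network(config: NetworkConfig, seed: int = 0) -> SleepWakeNet:
    """Construct an untrained network for the configured branches."""
    return SleepWakeNet(config, seed=seed)


def augment_batch(
    segments: np.ndarray, aug: AugmentationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Rescale each segment by an independent uniform draw in the range."""
    scales = rng.uniform(aug.scale_low, aug.scale_high, size=(segments.shape[0], 1))
    return segments * scales


def assemble_dataset(
    datas: list[EpochData],
    branches: tuple[str, ...] = (RESPIRATORY,),
    mode: str = "full",
) -> Dataset:
    """Pool preprocessed recordings into one epoch matrix.

    Keeps epochs retained by every requested branch's preprocessing chain
    and by the quality policy (``mode="clean"`` drops low-quality epochs,
    using each modality's own flag).
    """
    Xs: dict[str, list[np.ndarray]] = {b: [] for b in branches}
    ys, pids, eidx = [], [], []
    for d in datas:
        keep = np.ones(d.n_epochs, dtype=bool)
        for b in branches:
            retained = d.retained_card if b == CARDIAC else d.retained_resp
            flags = d.quality_card if b == CARDIAC else d.quality_resp
            keep &= quality_gate(retained, flags, mode)
        for b in branches:
            X = d.X_card if b == CARDIAC else d.X_resp
            Xs[b].append(X[keep])
        ys.append(d.stage[keep])
        pids.append(np.full(int(keep.sum()), d.patient_id))
        eidx.append(np.flatnonzero(keep))
    return Dataset(
        {b: np.concatenate(Xs[b]) if ys else np.empty((0, EPOCH_SAMPLES)) for b in branches},
        np.concatenate(ys).astype(int),
        np.concatenate(pids),
        np.concatenate(eidx),
    )


def _class_weights(y: np.ndarray) -> np.ndarray:
    """Inverse-frequency weights over the two classes."""
    counts = np.bincount(y, minlength=2).astype(float)
    if np.any(counts == 0):
        raise ValueError("training data must contain both classes")
    return y.size / (2.0 * counts)


def _eval_loss(model: SleepWakeNet, data: Dataset, weights: np.ndarray, batch: int = 4096) -> float:
    total, wsum = 0.0, 0.0
    for lo in range(0, len(data), batch):
        sl = slice(lo, lo + batch)
        logits = model.forward({k: v[sl] for k, v in data.X.items()})
        loss, _ = nn.weighted_cross_entropy(logits, data.y[sl], weights)
        w = weights[data.y[sl]].sum()
        total += loss * w
        wsum += w
    return total / max(wsum, 1e-12)


def train_network(
    model: SleepWakeNet,
    train: Dataset,
    val: Dataset,
    aug: AugmentationConfig | None = None,
    seed: int = 0,
    config: TrainingConfig = TrainingConfig(),
) -> dict:
    """Train in place with early stopping; returns the pass history.

    Each training pass iterates ``duplication_factor`` times over the
    shuffled data (the logical x4 duplication), drawing a fresh amplitude
    scale per segment per step when augmentation is on. The best
    validation-loss parameters are restored at the end.
    """
    rng = np.random.default_rng(seed)
    weights = _class_weights(train.y)
    opt = nn.Adam(model.params(), lr=config.lr)
    dup = aug.duplication_factor if aug else 1
    history: dict = {"train_loss": [], "val_loss": []}
    best_loss, best_state, since_best = np.inf, model.state(), 0

    n = len(train)
    for _ in range(config.max_passes):
        pass_loss, n_batches = 0.0, 0
        for _ in range(dup):
            order = rng.permutation(n)
            for lo in range(0, n, config.batch_size):
                idx = order[lo : lo + config.batch_size]
                Xb = {k: v[idx] for k, v in train.X.items()}
                if aug is not None:
                    for b in aug.apply_to:
                        if b in Xb:
                            Xb[b] = augment_batch(Xb[b], aug, rng)
                logits = model.forward(Xb, train=True, rng=rng)
                loss, dlogits = nn.weighted_cross_entropy(logits, train.y[idx], weights)
                model.backward(dlogits)
                opt.step(model.grads())
                pass_loss += loss
                n_batches += 1
        val_loss = _eval_loss(model, val, weights)
        history["train_loss"].append(pass_loss / max(n_batches, 1))
        history["val_loss"].append(val_loss)
        if val_loss < best_loss - 1e-6:
            best_loss, best_state, since_best = val_loss, model.state(), 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    model.load_state(best_state)
    history["best_val_loss"] = best_loss
    return history


def predict(model: SleepWakeNet, X: dict[str, np.ndarray], epoch_index: np.ndarray, patient_id: str = "") -> PredictionSeries:
    """Per-epoch probabilities and hard labels (tie at 0.5 -> sleep)."""
    proba = model.predict_proba(X)
    return PredictionSeries.from_probabilities(epoch_index, proba[:, WAKE], patient_id)


def predict_recording(
    model: SleepWakeNet, data: EpochData, mode: str = "full"
) -> PredictionSeries:
    """Predict one recording's retained epochs under a quality policy."""
    ds = assemble_dataset([data], model.config.branches, mode=mode)
    return predict(model, ds.X, ds.epoch_index, data.patient_id)


def _split_patients(
    patients: list[str], val_fraction: float, rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    n = len(patients)
    if n < 3:
        raise ValueError(f"need at least 3 patients to split, got {n}")
    n_train = int(round((1.0 - val_fraction) * n))
    n_train = min(max(n_train, 1), n - 1)
    order = rng.permutation(n)
    return (
        [patients[i] for i in order[:n_train]],
        [patients[i] for i in order[n_train:]],
    )


def pooled_kappa(model: SleepWakeNet, data: Dataset) -> float:
    """Cohen's kappa of predictions pooled over all epochs of a dataset."""
    proba = model.predict_proba(data.X)
    pred = np.where(proba[:, WAKE] > 0.5, WAKE, SLEEP)
    return float(cohen_kappa_score(data.y, pred))


def repeated_training_select(
    pool: list[EpochData],
    selection: list[EpochData],
    protocol: TrainingProtocol = TrainingProtocol(),
    net_config: NetworkConfig = NetworkConfig(),
    aug: AugmentationConfig | None = AugmentationConfig(),
    train_config: TrainingConfig = TrainingConfig(),
    mode: str = "full",
) -> tuple[SleepWakeNet, list[dict]]:
    """Train ``n_repeats`` networks on patient-level resplits; keep the best.

    The pool is restricted to patients with AHI below ``protocol.ahi_cap``;
    every repeat draws a fresh 70/30 patient split (seeded from
    ``seed_base + repeat``), trains a network, and scores pooled Cohen's
    kappa on the disjoint ``selection`` recordings. Ties break to the
    lowest repeat index. Returns ``(best_model, table)`` with one row per
    repeat (repeat, seed, kappa, train/validation patient ids).
    """
    pool = [d for d in pool if d.ahi < protocol.ahi_cap]
    patients = sorted({d.patient_id for d in pool})
    if len(patients) < 3:
        raise ValueError("fewer than 3 eligible patients: infeasible split")
    by_id = {d.patient_id: d for d in pool}
    sel_ds = assemble_dataset(selection, net_config.branches, mode=mode)

    best_model, best_kappa, table = None, -np.inf, []
    for rep in range(protocol.n_repeats):
        seed = protocol.seed_base + rep
        rng = np.random.default_rng(seed)
        train_ids, val_ids = _split_patients(patients, protocol.val_fraction, rng)
        train_ds = assemble_dataset([by_id[p] for p in train_ids], net_config.branches, mode=mode)
        val_ds = assemble_dataset([by_id[p] for p in val_ids], net_config.branches, mode=mode)
        model = build_network(net_config, seed=seed)
        train_network(model, train_ds, val_ds, aug=aug, seed=seed, config=train_config)
        kappa = pooled_kappa(model, sel_ds)
        table.append(
            {"repeat": rep, "seed": seed, "kappa": kappa, "train_patients": train_ids, "val_patients": val_ids}
        )
        if kappa > best_kappa:
            best_model, best_kappa = model, kappa
    assert best_model is not None
    return best_model, table


def fuse_multimodal(
    cardiac_model: SleepWakeNet,
    resp_model: SleepWakeNet,
    train: Dataset,
    val: Dataset,
    seed: int = 0,
    train_config: TrainingConfig = TrainingConfig(),
    dense_units: int | None = None,
) -> SleepWakeNet:
    """Combine two trained unimodal networks into a frozen-conv fusion.

    The convolutional stacks of both models are copied into a two-branch
    network and frozen; a fresh dense head is trained on the concatenated
    feature maps. The convolutional weights are bit-identical before and
    after fusion training.
    """
    cfg = replace(
        cardiac_model.config,
        branches=(CARDIAC, RESPIRATORY),
        dense_units=dense_units or cardiac_model.config.dense_units,
    )
    fused = SleepWakeNet(cfg, seed=seed)
    fused.branches[CARDIAC] = copy.deepcopy(cardiac_model.branches[CARDIAC])
    fused.branches[RESPIRATORY] = copy.deepcopy(resp_model.branches[RESPIRATORY])
    for b in fused.branches.values():
        b.freeze()
    train_network(fused, train, val, aug=None, seed=seed, config=train_config)
    return fused
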