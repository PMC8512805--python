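"""Minimal EDF interchange for respiratory waveforms.

The writer emits plain EDF (one or more uniformly sampled channels,
16-bit, per-channel physical scaling, 1 s data records) so recordings can
be exchanged with standard sleep-analysis tools; the reader goes through
MNE, which handles EDF/EDF+ headers robustly. A writer -> reader
round-trip agrees within 16-bit quantization of the physical range.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np

__all__ = ["write_edf", "read_edf"]


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(
    path: str | Path,
    signals: list[tuple[str, np.ndarray, float]],
    patient_id: str = "X",
    start: _dt.datetime | None = None,
) -> Path:
    """Write channels as 16-bit EDF with 1 s data records.

    ``signals`` is a list of ``(label, data, fs)``; each channel's
    sampling rate must be a positive integer (samples per 1 s record).
    Trailing samples beyond the last whole second are dropped.
    """
    path = Path(path)
    if not signals:
        raise ValueError("at least one signal is required")
    start = start or _dt.datetime(2000, 1, 1, 22, 0, 0)
    ns = len(signals)
    fss = []
    for label, data, fs in signals:
        if fs <= 0 or abs(fs - round(fs)) > 1e-9:
            raise ValueError(f"channel {label!r}: fs must be a positive integer, got {fs}")
        fss.append(int(round(fs)))
    n_records = min(int(np.asarray(d).size // f) for (_, d, _), f in zip(signals, fss))
    if n_records == 0:
        raise ValueError("signals shorter than one 1 s data record")

    digmin, digmax = -32768, 32767
    scaled, physmins, physmaxs = [], [], []
    for (label, data, _), fs in zip(signals, fss):
        x = np.asarray(data, dtype=float)[: n_records * fs]
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi == lo:
            hi = lo + 1.0
        physmins.append(lo)
        physmaxs.append(hi)
        dig = np.round((x - lo) / (hi - lo) * (digmax - digmin) + digmin)
        scaled.append(dig.astype("<i2"))

    header_bytes = 256 * (1 + ns)
    head = b"".join(
        [
            _field("0", 8),
            _field(patient_id, 80),
            _field("Startdate X", 80),
            _field(start.strftime("%d.%m.%y"), 8),
            _field(start.strftime("%H.%M.%S"), 8),
            _field(str(header_bytes), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field("1", 8),
            _field(str(ns), 4),
        ]
    )
    # signal header fields are stored field-major across channels
    for width, values in [
        (16, [s[0] for s in signals]),
        (80, [""] * ns),  # transducer
        (8, [""] * ns),  # physical dimension (none: keep raw units)
        (8, [f"{v:.6g}" for v in physmins]),
        (8, [f"{v:.6g}" for v in physmaxs]),
        (8, [str(digmin)] * ns),
        (8, [str(digmax)] * ns),
        (80, [""] * ns),  # prefiltering
        (8, [str(f) for f in fss]),
        (32, [""] * ns),
    ]:
        head += b"".join(_field(v, width) for v in values)

    with open(path, "wb") as fh:
        fh.write(head)
        for r in range(n_records):
            for dig, fs in zip(scaled, fss):
                fh.write(dig[r * fs : (r + 1) * fs].tobytes())
    return path


def read_edf(path: str | Path, channels: list[str] | None = None) -> dict[str, tuple[np.ndarray, float]]:
    """Read an EDF/EDF+ file; returns ``{label: (signal, fs)}``.

    ``channels`` optionally restricts (and validates) the labels to load;
    a miss raises with the available labels listed.
    """
    import mne  # deferred: MNE import is heavy

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    available = list(raw.ch_names)
    wanted = channels if channels is not None else available
    missing = [c for c in wanted if c not in available]
    if missing:
        raise KeyError(f"channels {missing} not found; available: {available}")
    data = raw.get_data(picks=wanted)
    fs = float(raw.info["sfreq"])
    return {c: (data[i], fs) for i, c in enumerate(wanted)}
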