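import numpy as np
import pytest

from somnoscreen import synthgen, types


@pytest.fixture(scope="session")
def tiny_recording() -> types.PatientRecording:
    """One 1 h moderate-AHI recording with artifacts and quality flags."""
    hyp = synthgen.generate_hypnogram(120, 0.2, 1.5, seed=301)
    events = synthgen.place_events(hyp, 20.0, seed=302)
    beats = synthgen.synth_beats(hyp, events, seed=303)
    sig, fs = synthgen.synth_respiration(hyp, events, seed=304)
    rec = types.PatientRecording(
        patient_id="P000",
        beat_times=beats,
        resp_signal=sig,
        resp_fs=fs,
        hypnogram=hyp,
        events=events,
        quality={},
        ahi=20.0,
    )
    return synthgen.corrupt_and_grade(rec, seed=305)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
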