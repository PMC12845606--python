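import numpy as np
import pandas as pd
import pytest

from synkick.emg_io import PHASES, CycleEvents, EmgRecording, TrialMeta


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_events() -> CycleEvents:
    """One cycle with the worked-example phase durations 0.4/0.2/0.3/0.5 s."""
    rows = []
    edges = [0.0, 0.4, 0.6, 0.9, 1.4]
    for p, phase in enumerate(PHASES):
        rows.append(
            {"cycle": 1, "phase": phase, "start_s": edges[p], "end_s": edges[p + 1]}
        )
    return CycleEvents(pd.DataFrame(rows))


def make_recording(signal: np.ndarray, fs: float = 2000.0) -> EmgRecording:
    m = signal.shape[0]
    return EmgRecording(
        muscle_labels=[f"ch{i}" for i in range(m)],
        fs=fs,
        signal=signal,
        meta=TrialMeta(subject="S1", group="control", session="pre"),
    )


@pytest.fixture
def make_rec():
    return make_recording
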