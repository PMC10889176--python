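import numpy as np
import pandas as pd
import pytest

from pupilhint.preprocess import UniformTrace


@pytest.fixture
def rng():
    return np.random.default_rng(20240201)


@pytest.fixture
def paper_timing_events():
    """One trial with the protocol timing: 3 s masker lead, 4 s tail."""
    return pd.DataFrame([{
        "trial_id": 1, "microphone": "Speech Omni", "configuration": "S0N0",
        "noise_on": 0.0, "sentence_on": 3.0, "sentence_off": 6.0,
        "noise_off": 10.0, "snr_db": 2.0,
    }])


def make_trace(values, fs=60.0, t0=0.0, valid=None):
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones(len(values), dtype=bool)
    return UniformTrace(t0=t0, fs=fs, values=values,
                        valid=np.asarray(valid, dtype=bool))


@pytest.fixture
def make_trace_fn():
    return make_trace
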