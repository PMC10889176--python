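"""Delimited-text I/O for pupil recordings, trial event logs, response logs and result tables.

All formats are plain CSV with a header row, ``.`` decimal separator and
time in seconds, so files are portable across locales and diffable. One
samples file exists per subject x condition; event and response logs hold
all of a subject's trials with microphone/configuration columns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: canonical condition labels
MICROPHONES = ("Speech Omni", "Opti Omni", "Split Dir")
CONFIGURATIONS = ("S0", "S0N0", "S0Nci", "S0Nctr")
NOISE_CONFIGURATIONS = ("S0N0", "S0Nci", "S0Nctr")

SAMPLE_COLUMNS = ("t", "diameter", "confidence")
EVENT_COLUMNS = (
    "trial_id", "microphone", "configuration",
    "noise_on", "sentence_on", "sentence_off", "noise_off", "snr_db",
)
RESPONSE_COLUMNS = ("trial_id", "microphone", "configuration", "snr_db", "correct")
LONG_COLUMNS = ("subject", "microphone", "configuration", "snr_db", "ppd_au", "n_epochs")


class FormatError(ValueError):
    """A file does not conform to one of the documented dialects."""


@dataclass
class RawPupilRecording:
    """An irregular pupil sample stream for one subject x condition.

    Parameters
    ----------
    subject_id : str
    microphone, configuration : str
        Condition labels (see :data:`MICROPHONES`, :data:`CONFIGURATIONS`).
    t : array of float
        Sample timestamps in seconds, strictly increasing.
    diameter : array of float
        Pupil diameter, non-negative. The unit (au or mm) is carried as
        metadata; the pipeline is unit-agnostic.
    confidence : array of float
        Per-sample tracker confidence in [0, 1].
    """

    subject_id: str
    microphone: str
    configuration: str
    t: np.ndarray
    diameter: np.ndarray
    confidence: np.ndarray
    unit: str = "au"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.diameter = np.asarray(self.diameter, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if not (len(self.t) == len(self.diameter) == len(self.confidence)):
            raise ValueError("t, diameter and confidence must have equal length")
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise FormatError("timestamps must be strictly increasing")
        if np.any(self.diameter < 0):
            raise FormatError("diameter must be non-negative")
        if np.any((self.confidence < 0) | (self.confidence > 1)):
            # tolerate slightly out-of-range confidence from upstream exports
            n_bad = int(np.sum((self.confidence < 0) | (self.confidence > 1)))
            warnings.warn(
                f"{n_bad} confidence value(s) outside [0, 1] clipped", stacklevel=2
            )
            log.warning("clipped %d out-of-range confidence values", n_bad)
            self.confidence = np.clip(self.confidence, 0.0, 1.0)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def condition(self) -> tuple[str, str]:
        return (self.microphone, self.configuration)


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")


def read_pupil_csv(path, subject_id: str = "", microphone: str = "",
                   configuration: str = "", unit: str = "au") -> RawPupilRecording:
    """Read a raw pupil samples CSV (columns ``t,diameter,confidence``).

    Out-of-range confidence is clipped with a warning; non-monotone
    timestamps or negative diameters are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise FormatError(f"{path}: file contains no samples")
    _require_columns(df, SAMPLE_COLUMNS, path)
    return RawPupilRecording(
        subject_id=subject_id, microphone=microphone, configuration=configuration,
        t=df["t"].to_numpy(), diameter=df["diameter"].to_numpy(),
        confidence=df["confidence"].to_numpy(), unit=unit,
    )


def write_pupil_csv(rec: RawPupilRecording, path) -> None:
    df = pd.DataFrame({
        "t": rec.t, "diameter": rec.diameter, "confidence": rec.confidence,
    })
    df.to_csv(path, index=False, float_format="%.9g")


def validate_events(df: pd.DataFrame, path="<events>") -> pd.DataFrame:
    """Enforce the trial-timing invariants on an event table.

    Each trial must satisfy noise_on <= sentence_on < sentence_off <= noise_off
    (under the study timing the masker leads the sentence by 3 s and trails
    it by 4 s, but any ordering-consistent timing is accepted).
    """
    _require_columns(df, EVENT_COLUMNS, path)
    bad = ~(
        (df["noise_on"] <= df["sentence_on"])
        & (df["sentence_on"] < df["sentence_off"])
        & (df["sentence_off"] <= df["noise_off"])
    )
    if bad.any():
        first = df.loc[bad, "trial_id"].iloc[0]
        raise FormatError(
            f"{path}: trial {first} violates event ordering "
            "(need noise_on <= sentence_on < sentence_off <= noise_off)"
        )
    return df.reset_index(drop=True)


def read_events(path) -> pd.DataFrame:
    """Read and validate a per-subject trial event log."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise FormatError(f"{path}: file contains no trials")
    _require_columns(df, EVENT_COLUMNS, path)
    for col in ("noise_on", "sentence_on", "sentence_off", "noise_off", "snr_db"):
        df[col] = df[col].astype(float)
    return validate_events(df, path)


def write_events(events: pd.DataFrame, path) -> None:
    validate_events(events, path)
    events.loc[:, list(EVENT_COLUMNS)].to_csv(path, index=False, float_format="%.9g")


def read_responses(path) -> pd.DataFrame:
    """Read a staircase response log (trial_id, condition, snr_db, correct)."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise FormatError(f"{path}: file contains no responses")
    _require_columns(df, RESPONSE_COLUMNS, path)
    df["snr_db"] = df["snr_db"].astype(float)
    df["correct"] = df["correct"].astype(int)
    if not df["correct"].isin((0, 1)).all():
        raise FormatError(f"{path}: 'correct' must be 0/1")
    return df.reset_index(drop=True)


def write_responses(responses: pd.DataFrame, path) -> None:
    _require_columns(responses, RESPONSE_COLUMNS, path)
    out = responses.loc[:, list(RESPONSE_COLUMNS)].copy()
    out["correct"] = out["correct"].astype(int)
    out.to_csv(path, index=False, float_format="%.9g")


def read_long_table(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    _require_columns(df, LONG_COLUMNS, path)
    for col in ("snr_db", "ppd_au"):
        df[col] = df[col].astype(float)
    return df


def write_long_table(table: pd.DataFrame, path) -> None:
    _require_columns(table, LONG_COLUMNS, path)
    table.loc[:, list(LONG_COLUMNS)].to_csv(path, index=False, float_format="%.9g")


def condition_slug(microphone: str, configuration: str) -> str:
    """Filesystem-safe slug for a condition, e.g. ``speech_omni__S0N0``."""
    return f"{microphone.lower().replace(' ', '_')}__{configuration}"
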