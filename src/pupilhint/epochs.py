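"""Per-sentence epoching, condition averaging and peak pupil dilation (PPD).

Epochs span -1 s to +4 s around sentence onset on the 60 Hz grid
(301 points). The 1 s pre-onset window, during which the masker is
already playing, provides the baseline that is subtracted from each
epoch; the PPD of a condition is the maximum of the across-epoch mean
curve between sentence onset and the average noise offset (+4 s).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .preprocess import MAX_REMOVED_FRACTION, UniformTrace

log = logging.getLogger(__name__)

EPOCH_START = -1.0
EPOCH_END = 4.0
EPOCH_FS = 60.0
MIN_BASELINE_VALID = 0.5


def epoch_grid(fs: float = EPOCH_FS, start: float = EPOCH_START,
               end: float = EPOCH_END) -> np.ndarray:
    """The fixed relative-time grid: start..end inclusive at fs."""
    n = int(round((end - start) * fs)) + 1
    return start + np.arange(n) / fs


@dataclass
class Epoch:
    """One baseline-corrected per-sentence trace on the fixed grid."""

    trial_id: object
    rel_time: np.ndarray
    values: np.ndarray          # diameter minus baseline, au
    valid: np.ndarray
    baseline_value: float
    removed_fraction: float     # pre-interpolation loss inside this window


@dataclass
class ConditionCurve:
    """Across-epoch mean curve and PPD for one subject x condition."""

    subject_id: str
    microphone: str
    configuration: str
    rel_time: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_per_point: np.ndarray
    valid: np.ndarray
    n_epochs_used: int

    @property
    def ppd(self) -> float:
        return peak_pupil_dilation(self).ppd


class PPDResult(NamedTuple):
    ppd: float
    peak_time: float


def _sample_on_grid(trace: UniformTrace, grid_t: np.ndarray,
                    mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation of trace values onto grid_t.

    A grid point is valid only if both bracketing trace samples satisfy
    ``mask``; points outside the trace span are invalid.
    """
    pos = (grid_t - trace.t0) * trace.fs
    lo = np.floor(pos).astype(int)
    hi = lo + 1
    inside = (lo >= 0) & (hi < len(trace))
    lo_c = np.clip(lo, 0, len(trace) - 1)
    hi_c = np.clip(hi, 0, len(trace) - 1)
    frac = pos - lo
    vals = trace.values[lo_c] * (1 - frac) + trace.values[hi_c] * frac
    # exact grid hits only need the one sample they land on
    exact = (lo >= 0) & (lo < len(trace)) & (np.abs(frac) < 1e-9)
    ok = (exact & mask[lo_c]) | (inside & mask[lo_c] & mask[hi_c])
    vals = np.where(exact, trace.values[lo_c], vals)
    return vals, ok


def epoch_trace(trace: UniformTrace, events: pd.DataFrame, *,
                fs: float = EPOCH_FS, start: float = EPOCH_START,
                end: float = EPOCH_END,
                max_removed: float = MAX_REMOVED_FRACTION,
                min_baseline_valid: float = MIN_BASELINE_VALID) -> list[Epoch]:
    """Cut one cleaned trace into baseline-corrected per-sentence epochs.

    Trials losing more than ``max_removed`` of their window (counted
    before interpolation) are excluded; trials reaching past the trace
    or with an unusable baseline window are skipped with a warning.
    """
    grid = epoch_grid(fs, start, end)
    epochs: list[Epoch] = []
    for row in events.itertuples():
        onset = float(row.sentence_on)
        grid_t = onset + grid
        if grid_t[0] < trace.t0 - 1e-9 or grid_t[-1] > trace.times[-1] + 1e-9:
            warnings.warn(f"trial {row.trial_id!r} extends beyond trace; skipped",
                          stacklevel=2)
            continue
        values, valid = _sample_on_grid(trace, grid_t, trace.valid)
        _, measured = _sample_on_grid(trace, grid_t, trace.measured)
        removed = 1.0 - float(np.mean(measured))
        if removed > max_removed:
            log.info("trial %r excluded: %.0f%% of samples removed",
                     row.trial_id, 100 * removed)
            continue
        base_sel = grid < 0
        base_valid = valid & base_sel
        if np.sum(base_valid) < min_baseline_valid * np.sum(base_sel):
            warnings.warn(f"trial {row.trial_id!r}: baseline window unusable; skipped",
                          stacklevel=2)
            continue
        baseline = float(np.mean(values[base_valid]))
        epochs.append(Epoch(
            trial_id=row.trial_id, rel_time=grid, values=values - baseline,
            valid=valid, baseline_value=baseline, removed_fraction=removed,
        ))
    return epochs


def average_epochs(epochs: list[Epoch], subject_id: str = "",
                   microphone: str = "", configuration: str = "") -> ConditionCurve:
    """Pointwise mean over epochs' valid samples, with per-point SD.

    Points with no contributing epoch are marked invalid.
    """
    if not epochs:
        raise ValueError("cannot average an empty epoch list")
    grid = epochs[0].rel_time
    vals = np.stack([e.values for e in epochs])
    valid = np.stack([e.valid for e in epochs])
    n = valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, np.where(valid, vals, 0.0).sum(axis=0) / np.maximum(n, 1), np.nan)
        sq = np.where(valid, (vals - mean) ** 2, 0.0).sum(axis=0)
        sd = np.where(n > 1, np.sqrt(sq / np.maximum(n - 1, 1)), 0.0)
    return ConditionCurve(
        subject_id=subject_id, microphone=microphone, configuration=configuration,
        rel_time=grid, mean=mean, sd=sd, n_per_point=n, valid=n > 0,
        n_epochs_used=len(epochs),
    )


def peak_pupil_dilation(curve: ConditionCurve,
                        window: tuple[float, float] = (0.0, EPOCH_END)) -> PPDResult:
    """Maximum of the mean curve between sentence onset and noise offset.

    Only valid points inside ``window`` are considered; the time of the
    peak is reported alongside the value.
    """
    sel = (curve.rel_time >= window[0]) & (curve.rel_time <= window[1]) & curve.valid
    if not np.any(sel):
        raise ValueError(
            f"no valid curve points in window for "
            f"{curve.subject_id}/{curve.microphone}/{curve.configuration}"
        )
    vals = np.where(sel, curve.mean, -np.inf)
    i = int(np.argmax(vals))
    return PPDResult(ppd=float(curve.mean[i]), peak_time=float(curve.rel_time[i]))
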