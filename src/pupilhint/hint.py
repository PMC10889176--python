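"""Adaptive speech-in-noise (HINT) staircase: simulation, timing and outcome.

The noise test presents 20 sentences with speech fixed at 65 dB SPL,
starting at +5 dB SNR. After each sentence the masker level is adjusted
one step: a correct repetition raises the masker (SNR decreases), an
incorrect one lowers it (SNR increases) — a 1-down/1-up rule converging
on the 50%-correct point. The quiet test runs the same logic on speech
level (dB HL) from 65 with no masker, yielding a speech reception
threshold (SRT). The masker leads each sentence by 3 s and trails it by
4 s, which also fixes the pupillometry trial timing.

Human sentence scoring is replaced by a Bernoulli listener with a
logistic psychometric function; externally scored response logs can be
fed to :func:`track_outcome` directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import EVENT_COLUMNS
from .synth import ListenerProfile, simulate_response

OUTCOME_RULES = ("mean_after_4", "reversal_mean")


@dataclass(frozen=True)
class StaircaseConfig:
    """Adaptive-track parameters.

    step is the masker/speech level adjustment in dB (the test protocol
    leaves it to the operator; 2 dB is the conventional choice).
    """

    n_sentences: int = 20
    start_snr: float = 5.0
    speech_level: float = 65.0
    step: float = 2.0
    noise_lead: float = 3.0
    noise_tail: float = 4.0
    sentence_duration: float = 3.0
    inter_trial_gap: float = 3.0
    outcome_rule: str = "mean_after_4"

    def __post_init__(self) -> None:
        if self.n_sentences < 2:
            raise ValueError("n_sentences must be >= 2")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.noise_lead < 0 or self.noise_tail < 0:
            raise ValueError("noise_lead and noise_tail must be >= 0")
        if self.outcome_rule not in OUTCOME_RULES:
            raise ValueError(f"unknown outcome rule {self.outcome_rule!r}")


@dataclass
class StaircaseTrack:
    """Presented levels and correctness for one adaptive list."""

    snr: np.ndarray            # presented SNR (noise) or speech level (quiet), dB
    correct: np.ndarray        # 0/1 per sentence
    cfg: StaircaseConfig
    in_quiet: bool = False

    def __post_init__(self) -> None:
        self.snr = np.asarray(self.snr, dtype=float)
        self.correct = np.asarray(self.correct, dtype=bool)

    @property
    def outcome(self) -> float:
        return track_outcome(self, self.cfg.outcome_rule)

    def timing(self, t_start: float = 0.0) -> pd.DataFrame:
        """Per-trial event times: masker lead/tail around each sentence."""
        cfg = self.cfg
        rows = []
        t = t_start
        for i, snr in enumerate(self.snr):
            noise_on = t
            sentence_on = noise_on + cfg.noise_lead
            sentence_off = sentence_on + cfg.sentence_duration
            noise_off = sentence_off + cfg.noise_tail
            rows.append((i + 1, "", "", noise_on, sentence_on,
                         sentence_off, noise_off, float(snr)))
            t = noise_off + cfg.inter_trial_gap
        return pd.DataFrame(rows, columns=list(EVENT_COLUMNS))


def _run_track(listener: ListenerProfile, cfg: StaircaseConfig,
               rng, start: float, harder_is_lower: bool) -> StaircaseTrack:
    rng = np.random.default_rng(rng)
    levels = np.empty(cfg.n_sentences)
    correct = np.empty(cfg.n_sentences, dtype=bool)
    level = float(start)
    for i in range(cfg.n_sentences):
        levels[i] = level
        correct[i] = simulate_response(listener, level, rng)
        # correct responses make the task harder, incorrect ones easier
        level += -cfg.step if correct[i] else cfg.step
    return StaircaseTrack(snr=levels, correct=correct, cfg=cfg,
                          in_quiet=not harder_is_lower)


def run_noise_track(listener: ListenerProfile, cfg: StaircaseConfig = StaircaseConfig(),
                    seed=None) -> StaircaseTrack:
    """Simulate one adaptive noise list.

    Speech stays fixed at ``cfg.speech_level`` dB SPL; the masker moves,
    so SNR drops by ``step`` after a correct repetition and rises after
    an incorrect one, starting from ``cfg.start_snr``.
    """
    return _run_track(listener, cfg, seed, cfg.start_snr, harder_is_lower=True)


def run_quiet_track(listener: ListenerProfile, cfg: StaircaseConfig = StaircaseConfig(),
                    seed=None) -> StaircaseTrack:
    """Simulate one adaptive quiet list on speech level (dB HL) from 65.

    The listener's ``srt_true`` is interpreted on the speech-level axis;
    the outcome is the SRT, the level for 50% correct repetition.
    """
    return _run_track(listener, cfg, seed, cfg.speech_level, harder_is_lower=True)


def track_outcome(track, rule: str = "mean_after_4") -> float:
    """Reduce a presented-level sequence to its SNR/SRT outcome.

    ``mean_after_4``: mean presented level from sentence 5 on (the first
    four sentences are the approach phase and are discarded).
    ``reversal_mean``: mean of levels at response-direction reversals.
    Accepts a :class:`StaircaseTrack` or any object with ``snr`` and
    ``correct`` sequences (e.g. a response-log row group).
    """
    snr = np.asarray(track.snr, dtype=float)
    correct = np.asarray(track.correct, dtype=bool)
    if rule == "mean_after_4":
        if len(snr) <= 4:
            raise ValueError("track too short for the mean-after-4 rule")
        return float(np.mean(snr[4:]))
    if rule == "reversal_mean":
        flips = np.flatnonzero(correct[1:] != correct[:-1]) + 1
        if len(flips) == 0:
            return float(snr[-1])
        return float(np.mean(snr[flips]))
    raise ValueError(f"unknown outcome rule {rule!r}")


def outcome_from_responses(responses: pd.DataFrame,
                           rule: str = "mean_after_4") -> float:
    """Outcome for one condition's response-log rows (sorted by trial_id)."""
    df = responses.sort_values("trial_id")

    class _T:
        snr = df["snr_db"].to_numpy()
        correct = df["correct"].to_numpy().astype(bool)

    return track_outcome(_T, rule)
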