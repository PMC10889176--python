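"""Synthetic pupil streams, trial logs and logistic listeners.

The generator emulates the data the analysis assumes: for each subject x
condition, an adaptive 20-sentence track driven by a logistic listener,
and a continuous pupil stream sampled at 120 Hz containing a slowly
drifting baseline, a task-evoked dilation pulse per sentence, Poisson
blinks (diameter collapse plus a confidence drop) and white sensor
noise. Condition effects are injected as parameter differences — a
per-configuration shift of the listener's true SRT and per-condition
evoked amplitudes — not as simulated acoustics.

Default condition effects follow the study design this package targets:
speech-in-noise is easiest with co-located noise (S0N0, mean SNR near
0 dB) and about 3 dB harder with lateral noise (S0Nci, S0Nctr), with a
task-evoked peak dilation near 0.05 au in every condition.

All randomness flows from one master seed through
``numpy.random.SeedSequence.spawn`` (one child per subject, then one per
condition), so any subject x condition subset is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .io import (CONFIGURATIONS, MICROPHONES, NOISE_CONFIGURATIONS,
                 RawPupilRecording, condition_slug, validate_events,
                 write_events, write_pupil_csv, write_responses)

#: gamma-family kernel shape for the task-evoked pupil response
EVOKED_SHAPE = 10.1


@dataclass(frozen=True)
class ListenerProfile:
    """A simulated listener with a logistic psychometric function.

    p(correct | snr) = lapse/2 + (1 - lapse) * logistic(4 * slope * (snr - srt_true))

    so ``slope`` is the probability gain per dB at the midpoint and
    ``srt_true`` is the 50%-correct SNR when ``lapse`` is 0.
    """

    srt_true: float
    slope: float = 0.15
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if not 0 <= self.lapse <= 0.1:
            raise ValueError("lapse must be in [0, 0.1]")

    def p_correct(self, snr) -> np.ndarray:
        z = 4.0 * self.slope * (np.asarray(snr, dtype=float) - self.srt_true)
        return self.lapse / 2 + (1 - self.lapse) * expit(z)


def simulate_response(listener: ListenerProfile, snr: float, seed) -> bool:
    """One Bernoulli sentence-repetition outcome at the given SNR."""
    rng = np.random.default_rng(seed)
    return bool(rng.random() < listener.p_correct(snr))


@dataclass(frozen=True)
class PupilGenParams:
    """Parameters of the synthetic pupil stream.

    Diameter is baseline + random-walk drift + evoked pulse + white
    noise; ``drift_sd`` is the random walk's standard deviation per
    square-root second. The evoked pulse is a smooth unimodal
    gamma-family kernel rising at ``sentence onset + evoked_latency``
    and peaking (at exactly ``evoked_amplitude``) at
    ``sentence onset + evoked_peak_time``. Blinks arrive as a Poisson
    process and collapse diameter to ~0 with confidence < 0.1.
    """

    fs_raw: float = 120.0
    baseline_mean: float = 4.0       # au
    drift_sd: float = 0.01           # au / sqrt(s)
    evoked_amplitude: float = 0.052  # au
    evoked_latency: float = 0.2      # s after sentence onset
    evoked_peak_time: float = 2.0    # s after sentence onset
    noise_sd: float = 0.01           # au
    blink_rate: float = 0.2          # blinks / s
    blink_duration_mean: float = 0.15  # s

    def __post_init__(self) -> None:
        if self.fs_raw <= 60:
            raise ValueError("fs_raw must exceed the 60 Hz target rate")
        if not (self.evoked_peak_time > self.evoked_latency >= 0):
            raise ValueError("need evoked_peak_time > evoked_latency >= 0")
        if min(self.drift_sd, self.noise_sd, self.blink_rate,
               self.blink_duration_mean) < 0:
            raise ValueError("variances, blink rate and duration must be >= 0")


@dataclass(frozen=True)
class StudyDesign:
    """Subjects x conditions layout: 1 quiet + |microphones| x 3 noise."""

    n_subjects: int = 8
    microphones: tuple[str, ...] = MICROPHONES
    configurations: tuple[str, ...] = NOISE_CONFIGURATIONS
    sentences_per_list: int = 20

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.sentences_per_list < 2:
            raise ValueError("sentences_per_list must be >= 2")

    @property
    def conditions(self) -> list[tuple[str, str]]:
        """(microphone, configuration) pairs; quiet runs on the default program."""
        quiet = [(self.microphones[0], "S0")]
        return quiet + [(m, c) for c in self.configurations for m in self.microphones]

    @property
    def subjects(self) -> list[str]:
        return [f"sub-{i + 1:02d}" for i in range(self.n_subjects)]


def evoked_kernel(t: np.ndarray, peak_time: float,
                  shape: float = EVOKED_SHAPE) -> np.ndarray:
    """Unit-peak gamma-family pulse: (t/tp)^n * exp(-n*(t/tp - 1)) for t >= 0."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / peak_time
    out[pos] = x ** shape * np.exp(-shape * (x - 1))
    return out


def _validate_timing(timing) -> tuple[float, float, float, float]:
    if isinstance(timing, dict):
        vals = (timing["noise_on"], timing["sentence_on"],
                timing["sentence_off"], timing["noise_off"])
    else:
        vals = tuple(timing)
    noise_on, sentence_on, sentence_off, noise_off = (float(v) for v in vals)
    if not (noise_on <= sentence_on < sentence_off <= noise_off):
        raise ValueError(
            "invalid trial timing: need noise_on <= sentence_on < "
            f"sentence_off <= noise_off, got ({noise_on}, {sentence_on}, "
            f"{sentence_off}, {noise_off})"
        )
    return noise_on, sentence_on, sentence_off, noise_off


def _gen_stream(params: PupilGenParams, t_start: float, t_end: float,
                sentence_onsets, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Continuous raw stream over [t_start, t_end] with one pulse per onset."""
    rng = np.random.default_rng(rng)
    n = int(np.floor((t_end - t_start) * params.fs_raw)) + 1
    t = t_start + np.arange(n) / params.fs_raw
    diameter = np.full(n, params.baseline_mean)
    if params.drift_sd > 0:
        steps = rng.normal(0.0, params.drift_sd / np.sqrt(params.fs_raw), n)
        diameter = diameter + np.cumsum(steps)
    tp = params.evoked_peak_time - params.evoked_latency
    for onset in np.atleast_1d(sentence_onsets):
        diameter += params.evoked_amplitude * evoked_kernel(
            t - (onset + params.evoked_latency), tp)
    if params.noise_sd > 0:
        diameter += rng.normal(0.0, params.noise_sd, n)
    confidence = np.full(n, 0.98)
    if params.blink_rate > 0:
        n_blinks = rng.poisson(params.blink_rate * (t_end - t_start))
        starts = np.sort(rng.uniform(t_start, t_end, n_blinks))
        durations = rng.exponential(params.blink_duration_mean, n_blinks)
        for s, d in zip(starts, durations):
            sel = (t >= s) & (t <= s + d)
            diameter[sel] = 0.0
            confidence[sel] = 0.02
    np.maximum(diameter, 0.0, out=diameter)
    return t, diameter, confidence


def gen_pupil_trial(params: PupilGenParams, timing, seed) -> RawPupilRecording:
    """Raw stream for a single trial, covering [noise_on, noise_off].

    ``timing`` is a mapping or 4-sequence (noise_on, sentence_on,
    sentence_off, noise_off); an inconsistent ordering is rejected.
    """
    noise_on, sentence_on, _, noise_off = _validate_timing(timing)
    t, d, c = _gen_stream(params, noise_on, noise_off, [sentence_on], seed)
    return RawPupilRecording(subject_id="", microphone="", configuration="",
                            t=t, diameter=d, confidence=c)


#: per-configuration shift of the listener's true SRT (dB), chosen so the
#: condition means sit near 0 / +3.1 / +3.5 dB for a 2.1 dB-SRT cohort
DEFAULT_CONFIG_SRT_OFFSETS = {"S0N0": -2.2, "S0Nctr": 1.0, "S0Nci": 1.4}
#: per-microphone SRT shift (dB): omni directivity trades off against
#: split-directional processing, with the optimized omni slightly worse
DEFAULT_MIC_SRT_OFFSETS = {"Speech Omni": -0.7, "Opti Omni": 1.0, "Split Dir": -0.3}

COHORT_SRT_MEAN = 2.1     # dB SNR, noise conditions
COHORT_SRT_SD = 3.0       # between-subject spread, dB
QUIET_SRT_MEAN = 45.0     # dB HL speech level, aided quiet SRT
QUIET_SRT_SD = 6.0
SUBJECT_AMPLITUDE_SD = 0.015  # between-subject evoked-amplitude spread, au


def default_listeners(design: StudyDesign, seed) -> dict[str, ListenerProfile]:
    """One logistic listener per subject, SRTs drawn around the cohort mean."""
    rng = np.random.default_rng(seed)
    return {
        s: ListenerProfile(srt_true=float(rng.normal(COHORT_SRT_MEAN, COHORT_SRT_SD)))
        for s in design.subjects
    }


def default_pupil_params(design: StudyDesign) -> dict[tuple[str, str], PupilGenParams]:
    """Identical evoked parameters in every condition (no true PPD effect)."""
    return {cond: PupilGenParams() for cond in design.conditions}


def gen_session(design: StudyDesign,
                listeners: dict[str, ListenerProfile],
                pupil_params: dict[tuple[str, str], PupilGenParams],
                seed: int,
                outdir,
                cfg=None,
                config_srt_offsets: dict[str, float] | None = None,
                mic_srt_offsets: dict[str, float] | None = None,
                subject_amplitude_sd: float = SUBJECT_AMPLITUDE_SD) -> Path:
    """Simulate and write a full dataset (samples, events, responses, manifest).

    For each subject x condition one adaptive track is run and one
    continuous pupil stream is generated with trials aligned to the
    track's timing. Listener difficulty per condition is the subject's
    base SRT plus configuration and microphone offsets; evoked amplitude
    gets a per-subject offset with SD ``subject_amplitude_sd``. Output is
    fully reproducible from ``seed``.
    """
    from .hint import StaircaseConfig, run_noise_track, run_quiet_track

    outdir = Path(outdir)
    missing = [c for c in design.conditions if c not in pupil_params]
    if missing:
        raise ValueError(f"missing pupil parameters for condition(s): {missing}")
    absent = [s for s in design.subjects if s not in listeners]
    if absent:
        raise ValueError(f"missing listener profile(s) for: {absent}")
    cfg = cfg or StaircaseConfig(n_sentences=design.sentences_per_list)
    config_srt_offsets = dict(DEFAULT_CONFIG_SRT_OFFSETS if config_srt_offsets is None
                              else config_srt_offsets)
    mic_srt_offsets = dict(DEFAULT_MIC_SRT_OFFSETS if mic_srt_offsets is None
                           else mic_srt_offsets)

    (outdir / "samples").mkdir(parents=True, exist_ok=True)
    (outdir / "events").mkdir(exist_ok=True)
    (outdir / "responses").mkdir(exist_ok=True)

    subject_seeds = np.random.SeedSequence(seed).spawn(design.n_subjects)
    sample_files: dict[str, str] = {}
    for subject, sseq in zip(design.subjects, subject_seeds):
        cond_seeds = sseq.spawn(len(design.conditions) + 1)
        amp_rng = np.random.default_rng(cond_seeds[-1])
        amp_offset = float(amp_rng.normal(0.0, subject_amplitude_sd))
        base = listeners[subject]
        all_events, all_responses = [], []
        for (mic, config), cseq in zip(design.conditions, cond_seeds):
            track_rng, pupil_rng = [np.random.default_rng(s) for s in cseq.spawn(2)]
            params = pupil_params[(mic, config)]
            amp = max(params.evoked_amplitude + amp_offset, 0.005)
            params = PupilGenParams(**{**asdict(params), "evoked_amplitude": amp})
            if config == "S0":
                quiet_listener = ListenerProfile(
                    srt_true=base.srt_true - COHORT_SRT_MEAN + QUIET_SRT_MEAN,
                    slope=base.slope, lapse=base.lapse)
                track = run_quiet_track(quiet_listener, cfg, track_rng)
            else:
                shifted = ListenerProfile(
                    srt_true=base.srt_true + config_srt_offsets.get(config, 0.0)
                    + mic_srt_offsets.get(mic, 0.0),
                    slope=base.slope, lapse=base.lapse)
                track = run_noise_track(shifted, cfg, track_rng)
            events = track.timing()
            events["microphone"] = mic
            events["configuration"] = config
            validate_events(events)
            t, d, c = _gen_stream(
                params, float(events["noise_on"].iloc[0]) - 1.5,
                float(events["noise_off"].iloc[-1]) + 1.5,
                events["sentence_on"].to_numpy(), pupil_rng)
            rec = RawPupilRecording(subject_id=subject, microphone=mic,
                                    configuration=config, t=t, diameter=d,
                                    confidence=c)
            fname = f"samples/{subject}__{condition_slug(mic, config)}.csv"
            write_pupil_csv(rec, outdir / fname)
            sample_files[f"{subject}|{mic}|{config}"] = fname
            all_events.append(events)
            all_responses.append(pd.DataFrame({
                "trial_id": np.arange(1, len(track.snr) + 1),
                "microphone": mic, "configuration": config,
                "snr_db": track.snr, "correct": track.correct.astype(int),
            }))
        write_events(pd.concat(all_events, ignore_index=True),
                     outdir / "events" / f"{subject}.csv")
        write_responses(pd.concat(all_responses, ignore_index=True),
                        outdir / "responses" / f"{subject}.csv")

    manifest = {
        "seed": int(seed),
        "design": {
            "n_subjects": design.n_subjects,
            "microphones": list(design.microphones),
            "configurations": list(design.configurations),
            "sentences_per_list": design.sentences_per_list,
        },
        "staircase": {k: (v if isinstance(v, (int, str)) else float(v))
                      for k, v in asdict(cfg).items()},
        "config_srt_offsets": {k: float(v) for k, v in config_srt_offsets.items()},
        "mic_srt_offsets": {k: float(v) for k, v in mic_srt_offsets.items()},
        "subject_amplitude_sd": float(subject_amplitude_sd),
        "listeners": {s: asdict(listeners[s]) for s in design.subjects},
        "pupil_params": {f"{m}|{c}": asdict(p)
                         for (m, c), p in pupil_params.items()},
        "samples": sample_files,
        "events": {s: f"events/{s}.csv" for s in design.subjects},
        "responses": {s: f"responses/{s}.csv" for s in design.subjects},
        "unit": "au",
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return outdir
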