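"""Simulate the adaptive speech-in-noise test for a logistic listener.

A 1-down/1-up staircase on the masker level: correct sentence
repetitions lower the SNR by one step, errors raise it, so the track
oscillates around the listener's 50%-correct point. The outcome is the
mean presented SNR from sentence 5 on.
"""

import numpy as np

from pupilhint import ListenerProfile, StaircaseConfig, run_noise_track, run_quiet_track

listener = ListenerProfile(srt_true=2.0, slope=0.15, lapse=0.02)
cfg = StaircaseConfig(step=2.0, start_snr=5.0)

track = run_noise_track(listener, cfg, seed=3)
print("presented SNRs (dB):", np.array2string(track.snr, precision=0))
print("correct:            ", track.correct.astype(int))
print(f"list outcome: {track.outcome:+.2f} dB SNR "
      f"(listener's true SRT: {listener.srt_true:+.2f} dB)")

rng = np.random.default_rng(3)
outcomes = [run_noise_track(listener, cfg, rng).outcome for _ in range(500)]
print(f"mean outcome over 500 lists: {np.mean(outcomes):+.2f} dB "
      f"(SD {np.std(outcomes):.2f}) -> the staircase is unbiased")

quiet = run_quiet_track(ListenerProfile(srt_true=45.0), cfg, seed=3)
print(f"quiet-test SRT: {quiet.outcome:.1f} dB HL "
      "(speech level staircase from 65 dB HL, threshold at 45)")
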