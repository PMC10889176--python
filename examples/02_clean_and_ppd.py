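"""Clean one recording and extract its peak pupil dilation (PPD).

Builds a single 20-trial condition, runs the full cleaning chain
(resample to 60 Hz, MAD blink rejection with 35/100 ms margins, 2.5 SD
outlier removal, gap interpolation, 50 ms smoothing), epochs it around
each sentence onset and reads the PPD off the average curve.
"""

import numpy as np

from pupilhint import (ListenerProfile, PupilGenParams, RawPupilRecording,
                       StaircaseConfig, average_epochs, epoch_trace,
                       peak_pupil_dilation, preprocess_recording,
                       run_noise_track)
from pupilhint.synth import _gen_stream

params = PupilGenParams(evoked_amplitude=0.06, blink_rate=0.2, noise_sd=0.01)
track = run_noise_track(ListenerProfile(srt_true=2.0), StaircaseConfig(), seed=7)
events = track.timing()
events["microphone"] = "Speech Omni"
events["configuration"] = "S0N0"

rng = np.random.default_rng(7)
t, d, c = _gen_stream(params, -1.5, float(events["noise_off"].iloc[-1]) + 1.5,
                      events["sentence_on"].to_numpy(), rng)
rec = RawPupilRecording("sub-01", "Speech Omni", "S0N0",
                        t=t, diameter=d, confidence=c)

trace = preprocess_recording(rec, events)
print(f"cleaning removed {trace.removed_fraction:.1%} of samples "
      "(blinks + margins + outliers, before interpolation)")

epochs = epoch_trace(trace, events)
curve = average_epochs(epochs, "sub-01", "Speech Omni", "S0N0")
res = peak_pupil_dilation(curve)
print(f"epochs used: {curve.n_epochs_used}/20")
print(f"PPD = {res.ppd:.4f} au at {res.peak_time:.2f} s after sentence onset "
      f"(injected evoked amplitude: {params.evoked_amplitude} au)")
# The PPD is the maximum of the baseline-corrected average curve between
# sentence onset and the average noise offset (+4 s); with 20 trials it
# recovers the injected amplitude to within a few percent.
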