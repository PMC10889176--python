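"""Generate a synthetic study dataset: 8 subjects, 10 conditions, 20 sentences.

Writes raw pupil sample streams, trial event logs, staircase response
logs and a manifest under ./example_dataset, all reproducible from the
master seed.
"""

from pupilhint import StudyDesign, default_listeners, default_pupil_params, gen_session

design = StudyDesign()  # 8 subjects, 3 microphones x 3 noise configs + quiet
listeners = default_listeners(design, seed=42)
params = default_pupil_params(design)
out = gen_session(design, listeners, params, seed=42, outdir="example_dataset")

print(f"dataset written to {out}")
print(f"conditions per subject: {len(design.conditions)} "
      "(1 quiet + 9 microphone x noise-configuration cells)")
for s, lst in list(listeners.items())[:3]:
    print(f"  {s}: true SRT {lst.srt_true:+.2f} dB SNR "
          f"(slope {lst.slope:.2f}/dB)")
# Each subject's files: samples/<subject>__<condition>.csv (t, diameter,
# confidence), events/<subject>.csv (trial timing) and
# responses/<subject>.csv (presented SNR + correctness per sentence).
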