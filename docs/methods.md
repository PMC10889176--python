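# Methods

This note documents the models behind `pupilhint`, the parameters that
matter, the choices made where the design was genuinely open, and what the
synthetic data can and cannot establish about real recordings.

## Study structure

The package targets within-subject designs where each participant completes
one quiet condition and a crossing of microphone programs
(Speech Omni, Opti Omni, Split Dir) with spatial noise configurations
(S0N0: noise co-located with speech; S0Nci: noise on the implant side;
S0Nctr: noise contralateral) — ten conditions with the defaults. Each
condition is one adaptive 20-sentence list with simultaneous pupil
recording. Trial timing is fixed: the masker starts 3 s before sentence
onset and ends 4 s after sentence offset.

## Adaptive staircase

A 1-down/1-up rule on the masker level (speech fixed at 65 dB SPL, start
+5 dB SNR) converges on the 50%-correct point of the psychometric function.
Parameters:

| parameter | default | unit | note |
|---|---|---|---|
| `step` | 2 | dB | the protocol leaves the step to the operator; 2 dB is the conventional choice for sentence tests and is configurable |
| `n_sentences` | 20 | — | one list |
| `start_snr` | +5 | dB | noise test |
| `speech_level` | 65 | dB SPL / dB HL | fixed speech (noise test) or starting level (quiet test) |
| `outcome_rule` | `mean_after_4` | — | mean presented level from sentence 5 on; `reversal_mean` (mean of levels at response reversals) is the alternative |

The outcome rule is a design choice: the protocol only fixes that a single
SNR is computed at the end of the list. Discarding the first four sentences
removes most of the approach phase from +5 dB; simulations in the test
suite show the resulting estimator is unbiased to within ±0.5 dB for
symmetric logistic listeners. When the start level is far from threshold
(e.g. the quiet test starting 20+ dB above SRT), the residual approach
phase still biases the mean upward by a few dB — a known property of short
adaptive blocks, not of this implementation.

Simulated listeners use
`p(correct | x) = λ/2 + (1 − λ)·σ(4 s (x − SRT))`, so `s` is the
probability gain per dB at the midpoint (default 0.15/dB, a steep
sentence-test slope) and `λ ≤ 0.1` a lapse rate. Human scoring of sentence
repetitions is out of scope; externally scored response logs can be fed to
`track_outcome` directly.

## Pupil preprocessing

Operators apply in a fixed, logged order: resample → blink detection →
margins → outlier removal → (per-epoch exclusion) → gap interpolation →
smoothing. Rationale: blink detection must precede deviation-based outlier
removal (blinks dominate the variance), and exclusion must be judged on
pre-interpolation validity or interpolation would hide data loss.

- **Resampling** to 60 Hz by linear interpolation on the grid
  `t0 + k/60`; grid points whose interpolated tracker confidence falls
  below the floor (default 0.6; the tracker exports confidence but no
  floor is standardized) are invalid.
- **Blink detection**: per-sample absolute dilation speed (the larger of
  the backward/forward first differences, scaled to au/s) thresholded at
  `median + k·MAD` with `k = 3` (common practice in pupillometry artifact
  rejection; configurable). Maximal runs of above-threshold or
  confidence-invalid samples form blink intervals. Generated blinks carry
  both signatures — diameter collapse and a confidence drop — so
  speed-based and confidence-based detectors both find them.
- **Margins**: 35 ms before to 100 ms after each interval is invalidated;
  overlapping expansions merge.
- **Outlier rule**: samples deviating more than 2.5 SD from the
  valid-sample mean are removed, and surviving valid islands shorter than
  40 ms are removed as unreliable fragments. The source protocol sentence
  couples the two clauses ambiguously; this reading (deviation outliers
  AND short fragments) follows the artifact-rejection literature the rule
  descends from, and the alternative (`islands=False`: deviation rule
  only) is a flag. SD scope is the per-trial segment when the pipeline
  drives the operator (the protocol is silent on scope).
- **Exclusion**: an epoch window losing strictly more than 50% of its
  samples (counted before interpolation) is dropped; exactly 50% is kept.
  The fraction is computed per epoch — the unit that is averaged — rather
  than per recording.
- **Interpolation**: interior invalid runs ≤ 0.3 s are bridged linearly
  and flagged as interpolated; edge runs are never extrapolated. The
  default bridges the margins around short blinks but not sustained signal
  loss. Whether removed points are interpolated before averaging or simply
  dropped is not fixed by the protocol; both are implemented
  (`interpolate=False` drops), default interpolates.
- **Smoothing**: centered 50 ms moving average over valid samples; the
  window shrinks at edges and across invalid neighbours so no data is
  invented.

## Epochs and PPD

Epochs span [−1, +4] s around sentence onset at 60 Hz (exactly 301
points). The baseline is the mean valid diameter over [−1, 0) — masker
on, sentence not yet started — and is subtracted pointwise; epochs whose
baseline window has under 50% valid samples are dropped. The condition
curve is the pointwise mean over epochs' valid samples with per-point SD,
and PPD is the maximum of that mean curve on [0, +4] s (the average noise
offset; recomputation from the actual event log is available). PPD is read
from the average curve, not averaged from per-trial peaks, which would be
upward-biased under noise.

## Synthetic data

Each subject × condition stream is: baseline (default 4 au) + random-walk
drift (0.01 au/√s) + one evoked pulse per sentence + white noise
(0.01 au), sampled at 120 Hz so the 60 Hz resampling is a genuine
operation. The pulse is a unit-peak gamma-family kernel
`(t/tp)^n e^{−n(t/tp−1)}` with shape `n = 10.1` (the standard task-evoked
pupil response shape), onset 0.2 s after sentence onset and peak at 2.0 s,
scaled to the condition's evoked amplitude (default 0.052 au, in the range
reported for speech-in-noise PPD). Blinks arrive as a Poisson process
(0.2/s, mean duration 0.15 s) collapsing diameter to 0 with confidence
0.02.

Condition effects are injected as parameter differences, not simulated
acoustics: per-configuration SRT shifts (S0N0 −2.2, S0Nctr +1.0, S0Nci
+1.4 dB around a 2.1 dB cohort mean, SD 3 dB) and per-microphone shifts
(Speech Omni −0.7, Opti Omni +1.0, Split Dir −0.3 dB) reproduce the
condition-mean pattern of bimodal-CI speech-in-noise data; evoked
amplitudes are equal across conditions (no true PPD effect) with
between-subject SD 0.015 au. The quiet test uses a 45 dB HL mean aided
SRT (SD 6 dB).

Randomness flows from one master seed via `SeedSequence.spawn` (subject →
condition → track/pupil), so any subset is reproducible and datasets are
byte-identical across runs.

**What the generator does not emulate**: gaze-dependent foreshortening,
luminance responses, slow vigilance drifts across a session, partial
blinks/half-closures, tracker dropout bursts, or any acoustic coupling
between SNR and pupil response. Passing tests therefore establish that the
pipeline recovers what its own model injects under realistic noise and
blink rates — not that the cleaning chain is optimal for any particular
eye tracker.

## Statistics

- **One-way RM-ANOVA**: classical within-subject decomposition after
  averaging over the other factor; `F = MS_factor/MS_error` on
  `(k−1, (k−1)(n−1))` df. No sphericity correction by default (none is
  standard in this literature's reporting); Greenhouse–Geisser is an
  option.
- **Two-way interaction model**: subject block plus configuration,
  microphone and interaction fixed effects against a single pooled
  residual stratum — for 8 subjects × 3 × 3 this gives numerator dfs
  (1, 2, 2, 4) and denominator df 56, the conditional-F layout of a
  random-intercept mixed fit on balanced data. The intercept row uses
  `F = N·ȳ²/MS_resid` on (1, 56) to complete that layout; its null
  calibration depends on the subject variance (it is reported for table
  completeness, not for inference). Separate per-term error strata
  (the textbook RM-ANOVA alternative) are available through the one-way
  decompositions. Under an exchangeable-normal null the factor and
  interaction F tests are exact; simulations in the test suite confirm
  type-I error within [0.04, 0.06] at α = 0.05.
- **Games–Howell**: Welch SE and Welch–Satterthwaite df per pair,
  p-values from the studentized-range distribution
  (`q = |Δ|/SE·√2`), symmetric in group order. scipy's
  `studentized_range` supplies the distribution; a vectorised
  critical-value path (`studentized_range_crit`, interpolated over a df
  grid to <0.1%) supports large simulations.
- **Spearman**: Pearson correlation of midranks; for n ≤ 10 without ties
  the two-sided p is exact by full permutation enumeration (cached per
  n), otherwise the t approximation on n−2 df. Exactness matters at this
  field's sample sizes (n = 8 subjects); at n = 8 the exact test's
  attainable level just below 0.05 is 0.046.
- **Shapiro–Wilk** (scipy) checks ANOVA residuals; **Bonferroni** divides
  α by the number of post hoc comparisons; **PTA** is the mean threshold
  over 500/1000/2000/4000 Hz.

## Numerical choices and degenerate inputs

Zero-variance samples are rejected by Shapiro–Wilk and Spearman with
explicit errors; ANOVA sums of squares at relative magnitude ≤ 1e−12 of
the total are treated as exactly zero so constant responses give F = 0
rather than 0/0; identical Games–Howell groups give p = 1. Epoch grid
points are valid only when both bracketing trace samples are valid (exact
grid hits need only their own sample). Files are written with fixed
formatting and sorted keys so equal inputs give byte-identical outputs.

## Problem sizes

The default end-to-end run (8 subjects × 10 conditions × 20 sentences,
~27 min of simulated recording per subject at 120 Hz) completes in about
10 s on one CPU; the calibration suites use 10⁴ simulations per null
(vectorised ANOVA cores and pair statistics) and 100 conditions × 20
trials for PPD recovery.

## Known limitations

- The MAD speed threshold intentionally flags the extreme tail of
  ordinary measurement noise as well as blinks (~5–10% of samples with
  margins at default noise); downstream interpolation bridges these short
  false positives, but removal fractions should be monitored on real data
  with different noise floors.
- The exact Spearman path enumerates n! permutations; n = 10 (3.6 M
  permutations) takes seconds on first use and is the practical ceiling.
- The quiet-test SRT from `mean_after_4` retains approach-phase bias when
  the start level is far above threshold (see above).
- No normalization of PPD across subjects is implemented; PPD is reported
  baseline-corrected in the recording's own units (au), and cross-study
  normalization schemes are out of scope.
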