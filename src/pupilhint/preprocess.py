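"""Pupil-trace cleaning: resampling, blink rejection, outlier removal, smoothing.

The chain transforms an irregular raw recording into a uniformly sampled
(default 60 Hz) diameter series with a validity mask, applying in order:

1. resample to a uniform grid, invalidating low-confidence samples;
2. blink detection on the dilation-speed signal via a median absolute
   deviation (MAD) threshold;
3. rejection margins of 35 ms before / 100 ms after each blink;
4. outlier removal: samples beyond 2.5 SD of the valid-sample mean, plus
   surviving valid islands shorter than 40 ms;
5. per-epoch exclusion when more than 50% of samples were removed
   (applied downstream, at epoching);
6. linear interpolation of short gaps;
7. a 50 ms centered moving average.

Every operator returns a new trace; the validity mask distinguishes samples
that were interpolated from samples that survived cleaning, so the loss
fraction that drives exclusion always refers to pre-interpolation validity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .io import RawPupilRecording

log = logging.getLogger(__name__)

TARGET_FS = 60.0
CONFIDENCE_FLOOR = 0.6
K_MAD = 3.0
PRE_MARGIN = 0.035
POST_MARGIN = 0.100
OUTLIER_Z = 2.5
MIN_ISLAND = 0.040
MAX_GAP = 0.3
SMOOTH_WINDOW = 0.050
MAX_REMOVED_FRACTION = 0.5


@dataclass
class UniformTrace:
    """A uniformly sampled pupil-diameter series with a validity mask.

    ``valid`` marks samples usable for averaging (including interpolated
    ones); ``interpolated`` marks the subset that was bridged rather than
    measured, so ``valid & ~interpolated`` is the pre-interpolation mask
    that the exclusion rule counts against.
    """

    t0: float
    fs: float
    values: np.ndarray
    valid: np.ndarray
    interpolated: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.interpolated is None:
            self.interpolated = np.zeros(len(self.values), dtype=bool)
        self.interpolated = np.asarray(self.interpolated, dtype=bool)
        if not (len(self.values) == len(self.valid) == len(self.interpolated)):
            raise ValueError("values, valid and interpolated must have equal length")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.fs

    @property
    def measured(self) -> np.ndarray:
        """Validity before interpolation (valid and not bridged)."""
        return self.valid & ~self.interpolated

    @property
    def removed_fraction(self) -> float:
        """Fraction of samples lost to cleaning, before any interpolation."""
        return 1.0 - float(np.mean(self.measured)) if len(self) else 0.0

    def copy(self) -> "UniformTrace":
        return UniformTrace(self.t0, self.fs, self.values.copy(),
                            self.valid.copy(), self.interpolated.copy())

    def index_of(self, t: float) -> float:
        return (t - self.t0) * self.fs


def resample_to_uniform(rec: RawPupilRecording, fs: float = TARGET_FS,
                        confidence_floor: float = CONFIDENCE_FLOOR) -> UniformTrace:
    """Linearly resample a raw recording onto a uniform grid.

    The grid is ``t0 + k/fs`` with ``t0`` at the first raw sample,
    covering the recorded span. Grid points whose interpolated tracker
    confidence falls below ``confidence_floor`` are marked invalid.
    """
    if len(rec) < 2 or (rec.t[-1] - rec.t[0]) <= 1.0 / fs:
        raise ValueError(
            f"recording span {rec.t[-1] - rec.t[0] if len(rec) else 0.0:.4f} s "
            f"too short to resample at {fs} Hz"
        )
    t0 = float(rec.t[0])
    n = int(np.floor((rec.t[-1] - t0) * fs)) + 1
    grid = t0 + np.arange(n) / fs
    values = np.interp(grid, rec.t, rec.diameter)
    conf = np.interp(grid, rec.t, rec.confidence)
    valid = conf >= confidence_floor
    return UniformTrace(t0=t0, fs=fs, values=values, valid=valid)


def dilation_speed(trace: UniformTrace) -> np.ndarray:
    """Per-sample absolute dilation speed (au/s).

    Each sample gets the larger of its backward and forward absolute
    first differences scaled by the sampling rate; edge samples use their
    single one-sided difference.
    """
    v = trace.values
    if len(v) < 2:
        return np.zeros(len(v))
    d = np.abs(np.diff(v)) * trace.fs
    speed = np.zeros(len(v))
    speed[0] = d[0]
    speed[-1] = d[-1]
    if len(v) > 2:
        speed[1:-1] = np.maximum(d[:-1], d[1:])
    return speed


def detect_blinks(trace: UniformTrace, k_mad: float = K_MAD) -> list[tuple[float, float]]:
    """Locate blink intervals via a MAD threshold on dilation speed.

    The threshold is ``median(speed) + k_mad * MAD(speed)`` computed over
    valid samples. Maximal runs of samples whose speed exceeds the
    threshold, or that are confidence-invalid, are returned as closed
    ``(start, end)`` time intervals.
    """
    if not np.any(trace.valid):
        warnings.warn("all samples invalid; no blinks detectable", stacklevel=2)
        return []
    if int(np.sum(trace.valid)) < 10:
        raise ValueError("need >= 10 valid samples for blink detection")
    speed = dilation_speed(trace)
    ref = speed[trace.valid]
    med = float(np.median(ref))
    mad = float(np.median(np.abs(ref - med)))
    threshold = med + k_mad * mad
    flagged = (speed > threshold) | ~trace.valid
    return _runs_to_intervals(flagged, trace)


def _runs_to_intervals(flagged: np.ndarray, trace: UniformTrace) -> list[tuple[float, float]]:
    intervals: list[tuple[float, float]] = []
    t = trace.times
    idx = np.flatnonzero(np.diff(np.concatenate(([0], flagged.astype(int), [0]))))
    for start, stop in zip(idx[::2], idx[1::2]):
        intervals.append((float(t[start]), float(t[stop - 1])))
    return intervals


def apply_blink_margins(trace: UniformTrace, intervals,
                        pre_margin: float = PRE_MARGIN,
                        post_margin: float = POST_MARGIN) -> UniformTrace:
    """Invalidate each blink interval extended by the rejection margins.

    Samples with time in ``[start - pre_margin, end + post_margin]`` are
    cleared from the validity mask; overlapping expansions merge
    naturally because they act on the same mask.
    """
    out = trace.copy()
    t = out.times
    for start, end in intervals:
        sel = (t >= start - pre_margin) & (t <= end + post_margin)
        out.valid[sel] = False
    return out


def remove_outliers(trace: UniformTrace, z: float = OUTLIER_Z,
                    min_len: float = MIN_ISLAND,
                    islands: bool = True) -> UniformTrace:
    """Remove deviation outliers and short valid fragments.

    A valid sample deviating more than ``z`` standard deviations from the
    valid-sample mean is invalidated. With ``islands=True`` (default),
    any remaining valid run strictly shorter than ``min_len`` seconds is
    then invalidated as an unreliable fragment; ``islands=False`` selects
    the alternative reading that only the deviation rule applies.

    The mean and SD are computed over the trace's valid samples (per
    trial segment when driven by the pipeline).
    """
    if int(np.sum(trace.valid)) < 10:
        raise ValueError("need >= 10 valid samples for outlier removal")
    out = trace.copy()
    v = out.values[out.valid]
    mean = float(np.mean(v))
    sd = float(np.std(v))
    if sd > 0:
        deviant = out.valid & (np.abs(out.values - mean) > z * sd)
        out.valid[deviant] = False
    if islands:
        min_samples = min_len * out.fs  # runs with fewer samples than this are fragments
        idx = np.flatnonzero(np.diff(np.concatenate(([0], out.valid.astype(int), [0]))))
        for start, stop in zip(idx[::2], idx[1::2]):
            if (stop - start) < min_samples:
                out.valid[start:stop] = False
    return out


def exclusion_check(trace: UniformTrace,
                    max_removed: float = MAX_REMOVED_FRACTION) -> bool:
    """Keep a trace (or epoch window) unless more than half its samples were removed.

    The boundary is strict: exactly 50% removed is kept.
    """
    return trace.removed_fraction <= max_removed


def interpolate_gaps(trace: UniformTrace, max_gap: float = MAX_GAP) -> UniformTrace:
    """Linearly bridge interior invalid runs no longer than ``max_gap`` seconds.

    Bridged samples become valid but are flagged ``interpolated`` so the
    removed fraction still reports pre-interpolation loss. Runs touching
    either trace edge are never extrapolated.
    """
    out = trace.copy()
    invalid = ~out.valid
    idx = np.flatnonzero(np.diff(np.concatenate(([0], invalid.astype(int), [0]))))
    for start, stop in zip(idx[::2], idx[1::2]):
        if start == 0 or stop == len(out):
            continue  # edge gap: no extrapolation
        if (stop - start) / out.fs > max_gap:
            continue
        left, right = start - 1, stop
        k = np.arange(start, stop)
        frac = (k - left) / (right - left)
        out.values[start:stop] = out.values[left] + frac * (out.values[right] - out.values[left])
        out.valid[start:stop] = True
        out.interpolated[start:stop] = True
    return out


def smooth_moving_average(trace: UniformTrace,
                          window: float = SMOOTH_WINDOW) -> UniformTrace:
    """Centered moving average over valid samples within +-window/2.

    The window shrinks at trace edges and across invalid neighbours, so
    no data is invented; invalid samples keep their stored values and
    remain invalid.
    """
    if window < 1.0 / trace.fs:
        raise ValueError("window must cover at least one sampling interval")
    out = trace.copy()
    half = int(np.floor(window / 2 * trace.fs))
    if half == 0:
        return out
    kernel = np.ones(2 * half + 1)
    vals = np.where(out.valid, out.values, 0.0)
    num = np.convolve(vals, kernel, mode="same")
    den = np.convolve(out.valid.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        smoothed = num / den
    out.values = np.where(out.valid & (den > 0), smoothed, out.values)
    return out


def preprocess_recording(rec: RawPupilRecording, events=None, *,
                         fs: float = TARGET_FS,
                         confidence_floor: float = CONFIDENCE_FLOOR,
                         k_mad: float = K_MAD,
                         pre_margin: float = PRE_MARGIN,
                         post_margin: float = POST_MARGIN,
                         z: float = OUTLIER_Z,
                         min_len: float = MIN_ISLAND,
                         islands: bool = True,
                         max_gap: float = MAX_GAP,
                         window: float = SMOOTH_WINDOW,
                         interpolate: bool = True) -> UniformTrace:
    """Run the full cleaning chain on one raw recording.

    When an event table is given, the outlier rule's mean/SD scope is the
    per-trial segment ``[noise_on, noise_off]``; otherwise the whole
    trace. Per-epoch exclusion happens later, at epoching, against the
    pre-interpolation mask this function preserves. ``interpolate=False``
    selects the drop-instead-of-bridge variant in which averaging simply
    skips removed points.
    """
    trace = resample_to_uniform(rec, fs=fs, confidence_floor=confidence_floor)
    intervals = detect_blinks(trace, k_mad=k_mad)
    trace = apply_blink_margins(trace, intervals, pre_margin, post_margin)
    if events is not None and len(events):
        for row in events.itertuples():
            i0 = max(0, int(np.ceil(trace.index_of(row.noise_on))))
            i1 = min(len(trace), int(np.floor(trace.index_of(row.noise_off))) + 1)
            if i1 - i0 < 10 or int(np.sum(trace.valid[i0:i1])) < 10:
                continue
            seg = UniformTrace(trace.t0 + i0 / trace.fs, trace.fs,
                               trace.values[i0:i1], trace.valid[i0:i1].copy())
            seg = remove_outliers(seg, z=z, min_len=min_len, islands=islands)
            trace.valid[i0:i1] = seg.valid
    else:
        trace = remove_outliers(trace, z=z, min_len=min_len, islands=islands)
    n_removed = int(np.sum(~trace.valid))
    log.info("cleaning removed %d/%d samples (%.1f%%)",
             n_removed, len(trace), 100 * n_removed / max(len(trace), 1))
    if interpolate:
        trace = interpolate_gaps(trace, max_gap=max_gap)
    trace = smooth_moving_average(trace, window=window)
    return trace
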