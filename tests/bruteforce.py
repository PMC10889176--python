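"""Independent loop-based reference implementations of the cleaning operators.

These mirror the documented contracts with direct per-sample loops and
no shared code with the package, so agreement on toy traces is a real
cross-check rather than a tautology.
"""

import math

import numpy as np


def bf_resample(t, d, c, fs=60.0, floor=0.6):
    t0 = t[0]
    n = math.floor((t[-1] - t0) * fs) + 1
    values, valid = [], []
    for k in range(n):
        tg = t0 + k / fs
        j = 0
        while j + 1 < len(t) and t[j + 1] < tg:
            j += 1
        if tg <= t[0]:
            v, cf = d[0], c[0]
        elif tg >= t[-1]:
            v, cf = d[-1], c[-1]
        else:
            while t[j + 1] < tg:
                j += 1
            w = (tg - t[j]) / (t[j + 1] - t[j])
            v = d[j] * (1 - w) + d[j + 1] * w
            cf = c[j] * (1 - w) + c[j + 1] * w
        values.append(v)
        valid.append(cf >= floor)
    return np.array(values), np.array(valid)


def bf_speed(values, fs):
    n = len(values)
    speed = [0.0] * n
    for i in range(n):
        cands = []
        if i > 0:
            cands.append(abs(values[i] - values[i - 1]) * fs)
        if i + 1 < n:
            cands.append(abs(values[i + 1] - values[i]) * fs)
        speed[i] = max(cands) if cands else 0.0
    return np.array(speed)


def bf_detect_blinks(t0, fs, values, valid, k_mad=3.0):
    speed = bf_speed(values, fs)
    ref = sorted(speed[i] for i in range(len(values)) if valid[i])
    med = _median(ref)
    mad = _median(sorted(abs(s - med) for s in ref))
    thr = med + k_mad * mad
    flagged = [(speed[i] > thr) or (not valid[i]) for i in range(len(values))]
    intervals, start = [], None
    for i, f in enumerate(flagged):
        if f and start is None:
            start = i
        if not f and start is not None:
            intervals.append((t0 + start / fs, t0 + (i - 1) / fs))
            start = None
    if start is not None:
        intervals.append((t0 + start / fs, t0 + (len(values) - 1) / fs))
    return intervals


def _median(sorted_vals):
    n = len(sorted_vals)
    if n == 0:
        return float("nan")
    return (sorted_vals[n // 2] if n % 2
            else 0.5 * (sorted_vals[n // 2 - 1] + sorted_vals[n // 2]))


def bf_margins(t0, fs, valid, intervals, pre=0.035, post=0.100):
    out = list(valid)
    for start, end in intervals:
        for i in range(len(valid)):
            ti = t0 + i / fs
            if start - pre <= ti <= end + post:
                out[i] = False
    return np.array(out)


def bf_outliers(values, valid, fs, z=2.5, min_len=0.040):
    vals = [values[i] for i in range(len(values)) if valid[i]]
    mean = sum(vals) / len(vals)
    sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / len(vals))
    out = list(valid)
    if sd > 0:
        for i in range(len(values)):
            if out[i] and abs(values[i] - mean) > z * sd:
                out[i] = False
    # invalidate valid islands strictly shorter than min_len
    i = 0
    while i < len(out):
        if out[i]:
            j = i
            while j < len(out) and out[j]:
                j += 1
            if (j - i) < min_len * fs:
                for m in range(i, j):
                    out[m] = False
            i = j
        else:
            i += 1
    return np.array(out)


def bf_interpolate(values, valid, fs, max_gap=0.3):
    vals, ok, interp = list(values), list(valid), [False] * len(values)
    i = 0
    while i < len(ok):
        if not ok[i]:
            j = i
            while j < len(ok) and not ok[j]:
                j += 1
            interior = i > 0 and j < len(ok)
            if interior and (j - i) / fs <= max_gap:
                for m in range(i, j):
                    w = (m - (i - 1)) / (j - (i - 1))
                    vals[m] = values[i - 1] * (1 - w) + values[j] * w
                    ok[m] = True
                    interp[m] = True
            i = j
        else:
            i += 1
    return np.array(vals), np.array(ok), np.array(interp)


def bf_smooth(values, valid, fs, window=0.050):
    half = math.floor(window / 2 * fs)
    out = list(values)
    for i in range(len(values)):
        if not valid[i]:
            continue
        acc, cnt = 0.0, 0
        for j in range(max(0, i - half), min(len(values), i + half + 1)):
            if valid[j]:
                acc += values[j]
                cnt += 1
        out[i] = acc / cnt
    return np.array(out)


def bf_baseline_correct(rel_time, values, valid):
    base_vals = [values[i] for i in range(len(values))
                 if valid[i] and rel_time[i] < 0]
    base = sum(base_vals) / len(base_vals)
    return np.array([v - base for v in values]), base


def bf_excluded(valid_before_interp):
    removed = sum(1 for v in valid_before_interp if not v) / len(valid_before_interp)
    return removed > 0.5
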