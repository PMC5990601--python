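"""Stride segmentation with bilateral verification.

Walking segments are turned into per-side stride sequences in four steps:

1. an autocorrelation filter rejects segments without stride-band
   periodicity on the non-affected thigh,
2. a hill-climbing peak detector finds stride events: candidate positions
   are maxima of the median-smoothed signal's derivative, each refined by
   iterative ascent to the nearest local maximum of the smoothed
   acceleration itself,
3. bilateral verification anchors on the non-affected side (the higher
   signal amplitude) and keeps exactly one affected peak — the affected
   acceleration maximum — per non-affected stride interval; surplus
   affected candidates are dropped and the last stride may be found on
   either side, so per-segment counts differ by at most one,
4. stride durations are bounded to [0.25, 3] s and segments with fewer
   than five consecutive in-bounds non-affected strides are rejected.
"""
from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks, medfilt

from .datatypes import SensorStream, Stride, StrideSequence, WalkingSegment

STRIDE_MIN_S = 0.25
STRIDE_MAX_S = 3.0


def periodicity_filter(y: np.ndarray, fs: float,
                       min_lag: float = STRIDE_MIN_S,
                       max_lag: float = STRIDE_MAX_S,
                       threshold: float = 0.3,
                       min_duration: float = 2.0) -> bool:
    """Keep a segment iff its vertical-axis autocorrelation shows periodicity.

    The normalized (unbiased) autocorrelation of the mean-removed signal is
    maximized over lags in the admissible stride band; segments shorter
    than ``min_duration`` or with zero variance are rejected.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < int(min_duration * fs):
        return False
    x = y - y.mean()
    denom = float(np.dot(x, x))
    # degenerate (numerically constant) signals carry no periodicity
    if denom <= 1e-10 * n * max(1.0, float(np.mean(y ** 2))):
        return False
    k_lo = max(1, int(np.ceil(min_lag * fs)))
    k_hi = min(n - 1, int(np.floor(max_lag * fs)))
    if k_hi < k_lo:
        return False
    best = -np.inf
    for k in range(k_lo, k_hi + 1):
        r = float(np.dot(x[:-k], x[k:])) / denom * (n / (n - k))
        if r > best:
            best = r
    return best >= threshold


def _ascend(ys: np.ndarray, i: int) -> int:
    """Iterative hill climb on ``ys`` to the nearest local maximum."""
    n = ys.size
    while True:
        left = ys[i - 1] if i > 0 else -np.inf
        right = ys[i + 1] if i < n - 1 else -np.inf
        if right > ys[i] and right >= left:
            i += 1
        elif left > ys[i]:
            i -= 1
        else:
            return i


def _smooth(y: np.ndarray, kernel: int) -> np.ndarray:
    kernel = int(kernel) | 1  # medfilt needs an odd kernel
    if y.size < kernel:
        return np.asarray(y, dtype=float)
    return medfilt(np.asarray(y, dtype=float), kernel)


def hill_climb_peaks(y: np.ndarray, fs: float, t: np.ndarray | None = None,
                     median_kernel: int = 5,
                     min_separation: float = STRIDE_MIN_S,
                     amp_quantile: float = 0.95,
                     amp_fraction: float = 0.3) -> np.ndarray:
    """Stride-event times from one thigh acceleration signal.

    Seeds are local maxima of the central-difference derivative of the
    median-smoothed signal above ``amp_fraction`` times its
    ``amp_quantile`` derivative amplitude; each seed climbs to the nearest
    local acceleration maximum.  Peaks closer than ``min_separation`` are
    thinned keeping the higher (ties: earlier) peak.  A flat signal yields
    no peaks.
    """
    y = np.asarray(y, dtype=float)
    if t is None:
        t = np.arange(y.size) / fs
    if y.size < 3:
        return np.empty(0)
    ys = _smooth(y, median_kernel)
    d = np.gradient(ys) * fs
    thr = amp_fraction * float(np.quantile(np.abs(d), amp_quantile))
    if thr <= 0.0:
        return np.empty(0)
    seeds, _ = find_peaks(d, height=thr)
    if seeds.size == 0:
        return np.empty(0)
    peaks = np.unique([_ascend(ys, int(i)) for i in seeds])
    # thin to the minimum separation, strongest first, earlier wins ties
    order = sorted(peaks, key=lambda i: (-ys[i], i))
    min_gap = min_separation * fs
    kept: list[int] = []
    for i in order:
        if all(abs(i - j) >= min_gap for j in kept):
            kept.append(i)
    return t[np.sort(kept)]


def pair_bilateral_strides(
    peaks_nonaff: np.ndarray,
    aff_signal: np.ndarray,
    t: np.ndarray,
    fs: float,
    segment: WalkingSegment | None = None,
    median_kernel: int = 5,
    min_separation: float = STRIDE_MIN_S,
    amp_quantile: float = 0.95,
    amp_fraction: float = 0.3,
) -> StrideSequence:
    """Verify affected-side strides against the non-affected anchor.

    Non-affected strides are the intervals between consecutive
    non-affected peaks.  For every such interval exactly one affected peak
    is kept: the hill-climb candidate with the highest affected
    acceleration amplitude, or — when no candidate falls inside — the
    affected acceleration maximum of the interval.  A trailing affected
    candidate after the last non-affected peak forms at most one extra
    affected stride.  The final affected stride's end is imputed from the
    last non-affected inter-peak interval, so per-side counts differ by at
    most one.
    """
    peaks_nonaff = np.asarray(peaks_nonaff, dtype=float)
    segment = segment or WalkingSegment(0, t.size, fs)
    if peaks_nonaff.size < 2:
        return StrideSequence(segment=segment)
    strides_na = [Stride("NonAff", float(a), float(b))
                  for a, b in zip(peaks_nonaff[:-1], peaks_nonaff[1:])]

    ys_aff = _smooth(np.asarray(aff_signal, dtype=float), median_kernel)
    cand = hill_climb_peaks(
        aff_signal, fs, t=t, median_kernel=median_kernel,
        min_separation=min_separation, amp_quantile=amp_quantile,
        amp_fraction=amp_fraction)

    def amp_at(time: float) -> float:
        return float(ys_aff[int(np.argmin(np.abs(t - time)))])

    aff_peaks: list[float] = []

    def add_peak(time: float) -> None:
        if all(abs(time - p) >= min_separation for p in aff_peaks):
            aff_peaks.append(time)

    for a, b in zip(peaks_nonaff[:-1], peaks_nonaff[1:]):
        inside = cand[(cand >= a) & (cand < b)]
        if inside.size:
            # surplus candidates with lower amplitudes are removed
            add_peak(float(max(inside, key=lambda c: (amp_at(c), -c))))
        else:
            # no detected candidate: fall back to the interval's affected
            # acceleration maximum so one peak per stride is ensured
            idx = np.flatnonzero((t >= a) & (t < b))
            if idx.size:
                add_peak(float(t[idx[np.argmax(ys_aff[idx])]]))
    trailing = cand[cand >= peaks_nonaff[-1]]
    if trailing.size:
        add_peak(float(max(trailing, key=amp_at)))
    aff_peaks = sorted(aff_peaks)

    last_interval = float(peaks_nonaff[-1] - peaks_nonaff[-2])
    strides_aff = []
    for j, start in enumerate(aff_peaks):
        end = aff_peaks[j + 1] if j + 1 < len(aff_peaks) else start + last_interval
        strides_aff.append(Stride("Aff", start, float(end)))
    return StrideSequence(segment=segment, strides_aff=strides_aff,
                          strides_nonaff=strides_na)


def _max_consecutive(flags: list[bool]) -> int:
    best = run = 0
    for f in flags:
        run = run + 1 if f else 0
        best = max(best, run)
    return best


def strides_from_segment(
    segment: WalkingSegment,
    thigh_nonaff: SensorStream,
    thigh_aff: SensorStream,
    median_kernel: int = 5,
    ac_threshold: float = 0.3,
    min_strides: int = 5,
    min_separation: float = STRIDE_MIN_S,
    amp_quantile: float = 0.95,
    amp_fraction: float = 0.3,
    stride_min_s: float = STRIDE_MIN_S,
    stride_max_s: float = STRIDE_MAX_S,
) -> tuple[StrideSequence | None, str | None]:
    """Full stride segmentation of one walking segment.

    Returns ``(sequence, None)`` on success or ``(None, reason)`` when the
    segment is rejected; reason codes: ``too_short``, ``aperiodic``,
    ``too_few_peaks``, ``min_strides``.
    """
    fs = thigh_nonaff.sampling_rate
    sl = slice(segment.start_sample, segment.end_sample)
    t = thigh_nonaff.t[sl]
    y_na = thigh_nonaff.axis("y")[sl]
    y_aff = thigh_aff.axis("y")[sl]
    if t.size < int(2.0 * fs):
        return None, "too_short"
    if not periodicity_filter(y_na, fs, threshold=ac_threshold):
        return None, "aperiodic"
    peaks_na = hill_climb_peaks(
        y_na, fs, t=t, median_kernel=median_kernel,
        min_separation=min_separation, amp_quantile=amp_quantile,
        amp_fraction=amp_fraction)
    if peaks_na.size < 2:
        return None, "too_few_peaks"
    seq = pair_bilateral_strides(
        peaks_na, y_aff, t, fs, segment=segment,
        median_kernel=median_kernel, min_separation=min_separation,
        amp_quantile=amp_quantile, amp_fraction=amp_fraction)

    in_bounds_na = [stride_min_s <= s.duration <= stride_max_s
                    for s in seq.strides_nonaff]
    if _max_consecutive(in_bounds_na) < min_strides:
        return None, "min_strides"
    seq.strides_nonaff = [s for s, ok in zip(seq.strides_nonaff, in_bounds_na)
                          if ok]
    seq.strides_aff = [s for s in seq.strides_aff
                       if stride_min_s <= s.duration <= stride_max_s]
    # verification guarantee: per-segment counts differ by at most one
    while len(seq.strides_aff) - len(seq.strides_nonaff) > 1:
        seq.strides_aff.pop()
    while len(seq.strides_nonaff) - len(seq.strides_aff) > 1:
        seq.strides_nonaff.pop()
    return seq, None
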