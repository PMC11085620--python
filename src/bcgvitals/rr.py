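"""R-R interval extraction, ectopic-beat correction, and windowing.

Ectopic (premature or delayed) beats distort both time- and
frequency-domain heart-rate-variability analysis, so the interval
sequence is screened before features are computed: an interval is an
outlier when it exceeds 1.3x or falls below 0.7x the series mean, and
each outlier is replaced by the median of the surrounding valid
intervals. Cleaned series are then cut into fixed-length windows
(five minutes by default), each window being one analysis sample.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, find_peaks, sosfiltfilt

from .core import RRSeries, Signal

__all__ = [
    "WindowedSample",
    "detect_beats",
    "beats_to_rr",
    "flag_outliers",
    "correct_outliers",
    "window_samples",
    "LOWER_FACTOR",
    "UPPER_FACTOR",
]

#: Outlier bounds relative to the series mean interval.
LOWER_FACTOR = 0.7
UPPER_FACTOR = 1.3


@dataclass
class WindowedSample:
    """Intervals falling inside one fixed-length window [start_s, end_s)."""

    intervals_ms: np.ndarray
    start_s: float
    end_s: float

    def __len__(self) -> int:
        return self.intervals_ms.size


def detect_beats(
    x: Signal,
    band_hz: tuple[float, float] = (0.7, 3.0),
    refractory_s: float = 0.3,
) -> np.ndarray:
    """Detect heartbeat times in a BCG waveform.

    The signal is band-limited to the cardiac band with a zero-phase
    Butterworth filter, then local maxima above an adaptive
    (median + MAD-based) prominence threshold are picked, enforcing a
    refractory period. Returns strictly increasing beat times in
    seconds; an empty array on flat input.
    """
    low, high = band_hz
    if x.fs <= 2.0 * high:
        raise ValueError("sampling rate must exceed twice the upper band edge")
    s = x.samples - np.mean(x.samples)
    if not np.any(s):
        return np.empty(0)
    sos = butter(4, [low, high], btype="bandpass", fs=x.fs, output="sos")
    filt = sosfiltfilt(sos, s)
    scale = np.median(np.abs(filt)) * 1.4826  # MAD -> sigma for Gaussian noise
    if scale == 0:
        scale = np.std(filt)
    if scale == 0:
        return np.empty(0)
    peaks, _ = find_peaks(
        filt, distance=max(int(round(refractory_s * x.fs)), 1), prominence=1.5 * scale
    )
    return peaks / x.fs


def beats_to_rr(times) -> RRSeries:
    """Successive beat-time differences as an R-R series in milliseconds."""
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        raise ValueError("need at least two beat times")
    if np.any(np.diff(times) <= 0):
        raise ValueError("beat times must be strictly increasing")
    intervals = np.diff(times) * 1000.0
    return RRSeries(intervals_ms=intervals, beat_times_s=times[:-1])


def flag_outliers(rr: RRSeries) -> RRSeries:
    """Mark intervals outside [0.7, 1.3]x the global series mean invalid.

    The mean is computed once over the whole input series, before any
    correction; interval values are untouched.
    """
    out = rr.copy()
    mean = float(np.mean(out.intervals_ms))
    out.valid_mask = (out.intervals_ms >= LOWER_FACTOR * mean) & (
        out.intervals_ms <= UPPER_FACTOR * mean
    )
    return out


def correct_outliers(rr: RRSeries, neighborhood: int = 30) -> RRSeries:
    """Replace each flagged interval by the median of its valid neighbours.

    Up to ``neighborhood`` nearest valid intervals (by index distance,
    window truncated at the edges) feed the median. Intervals with fewer
    than 3 valid neighbours are left untouched and stay flagged. After
    correction the bounds are re-checked once against the corrected
    series' mean, and any fresh violation is corrected the same way.
    """
    out = rr.copy()
    for _pass in range(2):
        bad = np.flatnonzero(~out.valid_mask)
        if bad.size == 0:
            break
        valid_idx = np.flatnonzero(out.valid_mask)
        for i in bad:
            if valid_idx.size < 3:
                continue
            order = np.argsort(np.abs(valid_idx - i), kind="stable")
            neighbours = valid_idx[order[:neighborhood]]
            new = float(np.median(out.intervals_ms[neighbours]))
            out.corrections.append((int(i), float(out.intervals_ms[i]), new))
            out.intervals_ms[i] = new
            out.valid_mask[i] = True
        # re-check: correction must keep intervals inside the bounds
        out = flag_outliers(out)
    return out


def window_samples(rr: RRSeries, window_s: float = 300.0) -> list[WindowedSample]:
    """Cut the series into consecutive non-overlapping windows.

    Windows are aligned to the first beat; an interval belongs to the
    window containing its terminating beat. The trailing partial window
    is dropped; a series shorter than one window yields an empty list
    with a warning.
    """
    if rr.beat_times_s is not None:
        t0 = rr.beat_times_s[0]
        ends = np.concatenate([rr.beat_times_s[1:], [rr.beat_times_s[-1] + rr.intervals_ms[-1] / 1000.0]])
    else:
        t0 = 0.0
        ends = np.cumsum(rr.intervals_ms) / 1000.0
    span = ends[-1] - t0
    n_windows = int(span // window_s)
    if n_windows == 0:
        warnings.warn("series shorter than one window; no samples produced", stacklevel=2)
        return []
    out = []
    for k in range(n_windows):
        lo, hi = t0 + k * window_s, t0 + (k + 1) * window_s
        sel = (ends > lo) & (ends <= hi)
        out.append(WindowedSample(intervals_ms=rr.intervals_ms[sel].copy(), start_s=lo, end_s=hi))
    return out
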