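"""Synthetic ballistocardiogram (BCG) generator with exact ground truth.

A BCG records the body's recoil from cardiac ejection of blood. The
generator emulates the structure such a recording has after optical
detection: a quasi-periodic cardiac pulse train (fundamental ~0.8-2 Hz),
a respiratory baseline oscillation (~0.1-0.5 Hz), slow drift, and
additive white noise. Every component is returned separately so that
downstream stages (decomposition, beat detection, HRV features, the
vital-sign estimator) can be scored against exact ground truth.

The cardiac pulse template is a Gaussian-windowed sinusoid — a damped
oscillation approximating the BCG I-J-K complex — whose global maximum
sits at the beat time, so detected peak times are directly comparable
to ground-truth beat times.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ConfigurationError, RRSeries, Signal

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_bcg",
    "generate_rr_series",
    "generate_ar_process",
]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic BCG recording.

    Defaults describe a resting adult: 72 beats/min with 25 ms of
    beat-to-beat jitter, 15 breaths/min, mild drift and noise.
    """

    duration_s: float = 600.0
    fs: float = 50.0
    hr_bpm: float = 72.0
    rr_brpm: float = 15.0
    hrv_jitter_ms: float = 25.0
    pulse_width_s: float = 0.25
    resp_amp: float = 0.4
    drift_amp: float = 0.15
    noise_sd: float = 0.05
    ectopic_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be > 0")
        if self.fs <= 0:
            raise ConfigurationError("fs must be > 0")
        if not (30.0 <= self.hr_bpm <= 220.0):
            raise ConfigurationError("hr_bpm must lie in [30, 220]")
        if not (4.0 <= self.rr_brpm <= 60.0):
            raise ConfigurationError("rr_brpm must lie in [4, 60]")
        for name in ("hrv_jitter_ms", "pulse_width_s", "resp_amp", "drift_amp", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not (0.0 <= self.ectopic_rate <= 1.0):
            raise ConfigurationError("ectopic_rate must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Exact truth emitted alongside a synthetic recording.

    ``component_signals`` (cardiac/respiratory/drift/noise) sum to the
    emitted waveform to machine precision.
    """

    beat_times_s: np.ndarray
    hr_series_bpm: np.ndarray
    rr_series_brpm: np.ndarray
    component_signals: dict = field(default_factory=dict)
    seed: int = 0


def _pulse_template(fs: float, width_s: float) -> np.ndarray:
    """Cardiac pulse: Gaussian bump carrying a faster damped wiggle.

    The bump concentrates spectral mass at the beat-train fundamental
    (so the heart-rate line dominates its harmonics) while the wiggle
    gives each cycle the multi-extremum I-J-K morphology. Global max is
    at the centre sample, i.e. the beat time.
    """
    half = max(int(round(3.0 * width_s * fs)), 1)
    t = np.arange(-half, half + 1) / fs
    sigma = max(0.8 * width_s, 1.0 / fs)
    osc_hz = 1.0 / max(width_s, 1.0 / fs)
    return np.exp(-0.5 * (t / sigma) ** 2) * (1.0 + 0.35 * np.cos(2.0 * np.pi * osc_hz * t))


def _jittered_beat_times(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    mean_ibi_s = 60.0 / config.hr_bpm
    n_beats = int(np.ceil(config.duration_s / mean_ibi_s)) + 2
    jitter = rng.normal(0.0, config.hrv_jitter_ms / 1000.0, size=n_beats)
    # keep intervals physiological even at large jitter
    intervals = np.clip(mean_ibi_s + jitter, 0.3 * mean_ibi_s, 1.7 * mean_ibi_s)
    times = np.concatenate(([0.0], np.cumsum(intervals)))[:-1]
    return times[times < config.duration_s]


def generate_bcg(config: SyntheticConfig) -> tuple[Signal, GroundTruth]:
    """Generate a synthetic BCG waveform plus its exact ground truth.

    The cardiac component is the pulse template placed at jittered beat
    times; the respiratory component a sinusoid at ``rr_brpm/60`` Hz; the
    drift a slow (0.01 Hz) oscillation; noise is white Gaussian. The four
    components sum to the emitted signal exactly.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs

    beat_times = _jittered_beat_times(config, rng)
    cardiac = np.zeros(n)
    template = _pulse_template(config.fs, config.pulse_width_s)
    half = (template.size - 1) // 2
    for bt in beat_times:
        center = int(round(bt * config.fs))
        lo, hi = center - half, center + half + 1
        s_lo, s_hi = max(lo, 0), min(hi, n)
        cardiac[s_lo:s_hi] += template[s_lo - lo : template.size - (hi - s_hi)]

    resp = config.resp_amp * np.sin(2.0 * np.pi * (config.rr_brpm / 60.0) * t)
    drift = config.drift_amp * np.sin(2.0 * np.pi * 0.01 * t + 0.5)
    noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else np.zeros(n)

    samples = cardiac + resp + drift + noise
    truth = GroundTruth(
        beat_times_s=beat_times,
        hr_series_bpm=np.full(max(int(config.duration_s // 300), 1), config.hr_bpm),
        rr_series_brpm=np.full(max(int(config.duration_s // 300), 1), config.rr_brpm),
        component_signals={
            "cardiac": cardiac,
            "respiratory": resp,
            "drift": drift,
            "noise": noise,
        },
        seed=config.seed,
    )
    return Signal(samples, config.fs), truth


def generate_rr_series(config: SyntheticConfig, n: int = 300) -> tuple[RRSeries, np.ndarray]:
    """Generate a jittered R-R interval series with optional ectopic beats.

    Intervals are centred on ``60000/hr_bpm`` ms with ``hrv_jitter_ms``
    spread. Each beat is independently replaced, with probability
    ``ectopic_rate``, by 0.5x or 1.6x its value (equal probability) —
    guaranteed to violate the 1.3x/0.7x-of-mean outlier bounds in both
    directions. Returns the series and the injected indices.
    """
    rng = np.random.default_rng(config.seed)
    mean_ms = 60000.0 / config.hr_bpm
    intervals = mean_ms + rng.normal(0.0, config.hrv_jitter_ms, size=n)
    intervals = np.clip(intervals, 0.75 * mean_ms, 1.25 * mean_ms)

    ectopic_idx = np.flatnonzero(rng.random(n) < config.ectopic_rate)
    factors = rng.choice([0.5, 1.6], size=ectopic_idx.size)
    intervals[ectopic_idx] = intervals[ectopic_idx] * factors

    beat_times = np.concatenate(([0.0], np.cumsum(intervals) / 1000.0))
    rr = RRSeries(intervals_ms=intervals, beat_times_s=beat_times[:-1])
    return rr, ectopic_idx


def generate_ar_process(
    coeffs, n: int, noise_sd: float = 1.0, seed: int = 0, burn_in: int = 500
) -> np.ndarray:
    """Stationary realization of an AR(p) process x_t = sum a_i x_{t-i} + e_t.

    Raises ``ValueError`` if the AR polynomial 1 - sum a_i z^{-i} has a
    root on or outside the unit circle (unstable process).
    """
    a = np.asarray(coeffs, dtype=float)
    if a.size:
        roots = np.roots(np.concatenate(([1.0], -a)))
        if np.any(np.abs(roots) >= 1.0 - 1e-12):
            raise ValueError("unstable AR coefficients: root on/outside unit circle")
    rng = np.random.default_rng(seed)
    total = n + burn_in
    e = rng.normal(0.0, noise_sd, size=total)
    if not a.size:
        return e[burn_in:]
    p = a.size
    x = np.zeros(total)
    for t in range(total):
        hist = x[max(t - p, 0) : t][::-1]
        x[t] = float(a[: hist.size] @ hist) + e[t]
    return x[burn_in:]
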