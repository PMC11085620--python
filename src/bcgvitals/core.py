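"""Core containers shared across the pipeline."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConfigurationError(ValueError):
    """Raised when a configuration field is invalid; names the field."""


@dataclass
class Signal:
    """A uniformly sampled real-valued waveform.

    Parameters
    ----------
    samples : ndarray
        Amplitudes in arbitrary units.
    fs : float
        Sampling rate in Hz.
    """

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("Signal samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Signal contains non-finite values")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs

    def copy(self) -> "Signal":
        return Signal(self.samples.copy(), self.fs)


@dataclass
class RRSeries:
    """Beat-to-beat (R-R) interval sequence in milliseconds.

    ``valid_mask[i]`` is False for intervals flagged as outliers;
    ``corrections`` records (index, old_ms, new_ms) replacements.
    """

    intervals_ms: np.ndarray
    beat_times_s: np.ndarray | None = None
    valid_mask: np.ndarray | None = None
    corrections: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals_ms = np.asarray(self.intervals_ms, dtype=float)
        if np.any(self.intervals_ms <= 0):
            raise ValueError("all R-R intervals must be positive")
        if self.beat_times_s is not None:
            self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.intervals_ms.size, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)

    def __len__(self) -> int:
        return self.intervals_ms.size

    def copy(self) -> "RRSeries":
        return RRSeries(
            self.intervals_ms.copy(),
            None if self.beat_times_s is None else self.beat_times_s.copy(),
            self.valid_mask.copy(),
            list(self.corrections),
        )
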