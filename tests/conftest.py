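import numpy as np
import pytest

from bcgvitals.core import Signal


@pytest.fixture(scope="session")
def two_tone():
    """Two oscillatory tones on a linear trend: the canonical
    decomposition fixture (fs = 100 Hz, 60 s)."""
    fs = 100.0
    t = np.arange(0, 60, 1 / fs)
    fast = np.sin(2 * np.pi * 1.2 * t)
    slow = np.sin(2 * np.pi * 0.25 * t)
    trend = 0.3 * t
    return {
        "signal": Signal(fast + slow + trend, fs),
        "fast": fast,
        "slow": slow,
        "trend": trend,
        "t": t,
        "fs": fs,
    }


def interior_corr(a: np.ndarray, b: np.ndarray, margin: int = 200) -> float:
    """Correlation over interior samples (boundary swings excluded)."""
    sl = slice(margin, -margin)
    a = a[sl] - a[sl].mean()
    b = b[sl] - b[sl].mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


@pytest.fixture(scope="session")
def clean_bcg():
    from bcgvitals.synthetic import SyntheticConfig, generate_bcg

    cfg = SyntheticConfig(
        duration_s=120.0, fs=100.0, hr_bpm=60.0, rr_brpm=15.0,
        hrv_jitter_ms=0.0, noise_sd=0.0, seed=0,
    )
    sig, truth = generate_bcg(cfg)
    return cfg, sig, truth
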