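"""Heart-rate-variability features per window.

Time-domain statistics (mean RR, SDNN, RMSSD, pNN50, HR) are computed
directly on the interval sequence. Frequency-domain band powers
(VLF 0.003-0.04 Hz, LF 0.04-0.15 Hz, HF 0.15-0.4 Hz) come from an
autoregressive power spectrum: the unevenly sampled tachogram is
cubic-spline resampled to a uniform grid (4 Hz default), an AR(16)
model is fitted to its biased autocorrelation by the Levinson-Durbin
recursion, and the model's rational spectrum is integrated over the
bands. A PCA step reduces the per-window feature matrix.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from sklearn.decomposition import PCA

from .rr import WindowedSample

__all__ = [
    "ARSpectrum",
    "HRVFeatureVector",
    "PCAReduction",
    "autocorrelation",
    "levinson_durbin",
    "ar_psd",
    "resample_tachogram",
    "time_domain_features",
    "freq_domain_features",
    "window_features",
    "pca_reduce",
    "UNDEFINED_RATIO",
]

#: Sentinel reported when HF power is zero and LF/HF is undefined.
UNDEFINED_RATIO = np.nan

VLF_BAND = (0.003, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)


@dataclass
class ARSpectrum:
    """Fitted AR(p) model and (optionally) its evaluated spectrum.

    ``coefficients`` are a_1..a_p in x_t = sum a_m x_{t-m} + e_t;
    ``noise_variance`` is the driving white-noise variance (ms^2 for
    tachograms); reflection coefficients all lie inside the unit circle
    for a positive-definite autocorrelation.
    """

    order: int
    coefficients: np.ndarray
    noise_variance: float
    reflection_coeffs: np.ndarray
    psd: np.ndarray | None = None
    freqs: np.ndarray | None = None


@dataclass
class HRVFeatureVector:
    mean_rr_ms: float = np.nan
    sdnn_ms: float = np.nan
    rmssd_ms: float = np.nan
    pnn50_fraction: float = np.nan
    hr_bpm: float = np.nan
    vlf_power: float = np.nan
    lf_power: float = np.nan
    hf_power: float = np.nan
    lf_hf_ratio: float = np.nan

    FIELDS = (
        "mean_rr_ms", "sdnn_ms", "rmssd_ms", "pnn50_fraction", "hr_bpm",
        "vlf_power", "lf_power", "hf_power", "lf_hf_ratio",
    )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.FIELDS], dtype=float)


@dataclass
class PCAReduction:
    components: np.ndarray  # (n_kept, n_features) orthonormal loadings
    explained_variance_fractions: np.ndarray
    n_kept: int
    center: np.ndarray
    scales: np.ndarray = field(default=None)


def autocorrelation(x, max_lag: int) -> np.ndarray:
    """Biased sample autocorrelation r_0..r_max_lag (mean removed,
    divided by n)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if max_lag >= n:
        raise ValueError("max_lag must be smaller than the series length")
    xc = x - x.mean()
    full = np.correlate(xc, xc, mode="full")[n - 1 :]
    return full[: max_lag + 1] / n


def levinson_durbin(r, order: int = 16) -> ARSpectrum:
    """Solve the Yule-Walker equations by the Levinson-Durbin recursion.

    Returns AR coefficients a_1..a_p, reflection coefficients k_1..k_p,
    and the prediction-error (noise) variance r_0 * prod(1 - k_i^2).
    Raises ``ValueError`` naming the failing stage when the
    autocorrelation sequence is not positive definite.
    """
    r = np.asarray(r, dtype=float)
    if r[0] <= 0:
        raise ValueError("autocorrelation r[0] must be positive (degenerate input)")
    if order >= r.size:
        raise ValueError("order must be < len(r)")
    a = np.zeros(order)
    k = np.zeros(order)
    err = r[0]
    for m in range(1, order + 1):
        acc = r[m] - np.dot(a[: m - 1], r[m - 1 : 0 : -1])
        km = acc / err
        if abs(km) >= 1.0:
            raise ValueError(
                f"non-positive-definite autocorrelation at stage {m}: |k|={abs(km):.3g} >= 1"
            )
        a_new = a.copy()
        a_new[m - 1] = km
        a_new[: m - 1] = a[: m - 1] - km * a[m - 2 :: -1][: m - 1]
        a = a_new
        k[m - 1] = km
        err *= 1.0 - km**2
        if err <= 0:
            raise ValueError(f"prediction error vanished at stage {m}")
    return ARSpectrum(order=order, coefficients=a, noise_variance=float(err),
                      reflection_coeffs=k)


def ar_psd(spec: ARSpectrum, fs: float, n_freqs: int = 1024) -> ARSpectrum:
    """Evaluate the AR model's power spectral density.

    psd(f) = sigma^2 / (fs * |1 - sum a_m exp(-i 2 pi f m / fs)|^2)
    on a uniform grid over [0, fs/2]. This is the two-sided density
    evaluated at non-negative frequencies (flat sigma^2/fs for order 0);
    band powers double it to count the mirrored negative-frequency half,
    so 2 * integral over [0, fs/2] recovers the process variance.
    """
    freqs = np.linspace(0.0, fs / 2.0, n_freqs)
    m = np.arange(1, spec.order + 1)
    phase = np.exp(-2j * np.pi * np.outer(freqs, m) / fs)
    denom = np.abs(1.0 - phase @ spec.coefficients.astype(complex)) ** 2
    psd = spec.noise_variance / (fs * denom)
    return ARSpectrum(
        order=spec.order,
        coefficients=spec.coefficients,
        noise_variance=spec.noise_variance,
        reflection_coeffs=spec.reflection_coeffs,
        psd=psd,
        freqs=freqs,
    )


def resample_tachogram(w: WindowedSample, fs_out: float = 4.0) -> np.ndarray:
    """Cubic-spline resample the interval tachogram to a uniform grid.

    Each interval is placed at its terminating beat time (cumulative sum
    within the window); values are interval lengths in ms.
    """
    if len(w) < 4:
        raise ValueError("need at least 4 intervals to resample")
    t = np.cumsum(w.intervals_ms) / 1000.0
    grid = np.arange(t[0], t[-1], 1.0 / fs_out)
    return CubicSpline(t, w.intervals_ms)(grid)


def time_domain_features(w: WindowedSample) -> HRVFeatureVector:
    """Mean RR, SDNN, RMSSD, pNN50 and HR for one window."""
    iv = np.asarray(w.intervals_ms, dtype=float)
    if iv.size < 2:
        raise ValueError("need at least 2 intervals")
    diff = np.diff(iv)
    mean_rr = float(iv.mean())
    return HRVFeatureVector(
        mean_rr_ms=mean_rr,
        sdnn_ms=float(iv.std(ddof=0)),
        rmssd_ms=float(np.sqrt(np.mean(diff**2))),
        pnn50_fraction=float(np.mean(np.abs(diff) > 50.0)),
        hr_bpm=60000.0 / mean_rr,
    )


def _band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    lo, hi = band
    sel = (freqs >= lo) & (freqs <= hi)
    if sel.sum() < 2:
        return 0.0
    # factor 2: one-sided band power from the two-sided density
    return float(2.0 * np.trapezoid(psd[sel], freqs[sel]))


def freq_domain_features(spec: ARSpectrum, resampled_fs: float = 4.0) -> HRVFeatureVector:
    """VLF/LF/HF band powers (ms^2) and LF/HF ratio from an AR spectrum.

    ``spec`` must be fitted on the evenly resampled tachogram; if its
    psd has not been evaluated yet it is evaluated here.
    """
    if spec.psd is None:
        spec = ar_psd(spec, resampled_fs)
    vlf = _band_power(spec.freqs, spec.psd, VLF_BAND)
    lf = _band_power(spec.freqs, spec.psd, LF_BAND)
    hf = _band_power(spec.freqs, spec.psd, HF_BAND)
    ratio = lf / hf if hf > 0 else UNDEFINED_RATIO
    return HRVFeatureVector(vlf_power=vlf, lf_power=lf, hf_power=hf, lf_hf_ratio=ratio)


def window_features(w: WindowedSample, ar_order: int = 16, resample_hz: float = 4.0) -> HRVFeatureVector:
    """Full time- plus frequency-domain feature vector for one window."""
    td = time_domain_features(w)
    tach = resample_tachogram(w, resample_hz)
    max_lag = min(ar_order, tach.size - 1)
    spec = levinson_durbin(autocorrelation(tach, max_lag), order=max_lag)
    fd = freq_domain_features(spec, resample_hz)
    td.vlf_power, td.lf_power, td.hf_power = fd.vlf_power, fd.lf_power, fd.hf_power
    td.lf_hf_ratio = fd.lf_hf_ratio
    return td


def pca_reduce(feature_matrix: np.ndarray, variance_target: float = 0.95,
               standardize: bool = True) -> tuple[np.ndarray, PCAReduction]:
    """Project a (windows x features) matrix onto its leading principal
    components, keeping the smallest count whose cumulative explained
    variance reaches ``variance_target``.

    Features are z-scored first (mixed units: ms, ms^2, ratios);
    zero-variance columns raise unless the whole matrix is degenerate.
    """
    X = np.asarray(feature_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 windows")
    center = X.mean(axis=0)
    scales = X.std(axis=0, ddof=0)
    if np.all(scales == 0):
        raise ValueError("zero-variance feature matrix")
    if standardize:
        safe = np.where(scales > 0, scales, 1.0)
        Xs = (X - center) / safe
    else:
        safe = np.ones(X.shape[1])
        Xs = X - center
    pca = PCA()
    scores = pca.fit_transform(Xs)
    frac = pca.explained_variance_ratio_
    n_kept = int(np.searchsorted(np.cumsum(frac), variance_target) + 1)
    n_kept = min(n_kept, frac.size)
    red = PCAReduction(
        components=pca.components_[:n_kept],
        explained_variance_fractions=frac[:n_kept],
        n_kept=n_kept,
        center=center,
        scales=safe,
    )
    return scores[:, :n_kept], red
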