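"""Empirical mode decomposition (EMD), ensemble EMD, and a
complete-ensemble adaptive-noise variant (DEMA).

EMD adaptively splits a non-stationary signal into intrinsic mode
functions (IMFs): oscillatory components whose extrema and
zero-crossing counts differ by at most one and whose upper/lower
envelope mean is (near) zero. Sifting repeatedly subtracts the
cubic-spline envelope mean until both IMF conditions and a
standard-deviation stopping criterion hold; the extracted IMF is
subtracted from the signal and the procedure recurses on the remainder
until it is monotone or has too few extrema. The decomposition is
complete by construction: the IMFs plus the final residue reconstruct
the input exactly.

Plain EMD suffers from mode mixing — oscillations of one timescale
leaking across IMFs — especially on noisy data. Ensemble EMD (EEMD)
decomposes many white-noise-perturbed copies and averages IMFs by
index, trading exact reconstruction for reduced mixing (the retained
noise shrinks as 1/sqrt(N)). The adaptive-noise variant implemented in
:func:`dema` recovers exact reconstruction: at each stage it averages
only the *first* mode of the current residue perturbed by the matching
EMD mode of stored noise realizations, with the noise amplitude
re-scaled to the residue's standard deviation, then subtracts that
averaged mode and recurses.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .core import Signal

__all__ = [
    "SiftingConfig",
    "EnsembleConfig",
    "IMFSet",
    "envelope_mean",
    "is_imf",
    "sift",
    "sd_criterion",
    "emd",
    "eemd",
    "dema",
    "mode_mixing_index",
    "dominant_frequency",
    "band_partial",
]


@dataclass
class SiftingConfig:
    """Sifting controls.

    sd_threshold is the stopping value for the sift-to-sift standard
    deviation criterion (classical range 0.2-0.3); boundary selects the
    envelope end-condition strategy ("mirror" reflects extrema about the
    signal ends before spline fitting).
    """

    sd_threshold: float = 0.2
    max_sift_iters: int = 10
    max_imfs: int = 0  # 0 = unlimited
    boundary: str = "mirror"
    min_extrema: int = 2  # per side (maxima and minima) below which decomposition stops
    mean_tol: float = 0.1

    def __post_init__(self) -> None:
        if self.sd_threshold <= 0:
            raise ValueError("sd_threshold must be > 0")
        if self.max_sift_iters < 1:
            raise ValueError("max_sift_iters must be >= 1")


@dataclass
class EnsembleConfig:
    """Ensemble controls: noise amplitude as a fraction of the source
    standard deviation (epsilon), ensemble size N, and the RNG seed."""

    noise_amplitude: float = 0.2
    ensemble_size: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be >= 0")
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")


@dataclass
class IMFSet:
    """Ordered IMFs c_1..c_n plus the residue r_n.

    ``sift_counts[i]`` is the number of sift iterations spent on IMF i;
    a negative count flags an IMF returned at the iteration cap without
    converging. For method "EMD" and "DEMA" the IMFs and residue sum to
    the source signal exactly (up to float association).
    """

    imfs: list
    residue: Signal
    sift_counts: list = field(default_factory=list)
    method: str = "EMD"

    def __len__(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.samples.copy()
        for c in self.imfs:
            out += c.samples
        return out

    def as_matrix(self) -> np.ndarray:
        """(n_imfs + 1, n_samples) array; last row is the residue."""
        rows = [c.samples for c in self.imfs] + [self.residue.samples]
        return np.vstack(rows)


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (plateaus collapsed
    onto their trailing edge via forward-filled slope signs)."""
    s = np.sign(np.diff(x))
    nz = s != 0
    if not nz.any():
        empty = np.empty(0, dtype=int)
        return empty, empty
    pos = np.maximum.accumulate(np.where(nz, np.arange(s.size), -1))
    filled = np.where(pos >= 0, s[np.maximum(pos, 0)], 0.0)
    change = np.diff(filled)
    maxima = np.flatnonzero(change < 0) + 1
    minima = np.flatnonzero(change > 0) + 1
    return maxima, minima


def _zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(s)))


def _mirrored_knots(idx: np.ndarray, vals: np.ndarray, n: int, n_mirror: int = 2):
    """Reflect up to ``n_mirror`` extrema about each end of [0, n-1],
    skipping extrema sitting exactly on a boundary sample."""
    ts = idx.astype(float)
    lsrc, lval = ts[: n_mirror + 1], vals[: n_mirror + 1]
    lkeep = lsrc > 0
    left_t = (-lsrc[lkeep])[:n_mirror]
    left_v = lval[lkeep][:n_mirror]
    rsrc, rval = ts[-(n_mirror + 1):], vals[-(n_mirror + 1):]
    rkeep = rsrc < n - 1
    right_t = (2.0 * (n - 1) - rsrc[rkeep])[-n_mirror:]
    right_v = rval[rkeep][-n_mirror:]
    t = np.concatenate([left_t[::-1], ts, right_t[::-1]])
    v = np.concatenate([left_v[::-1], vals, right_v[::-1]])
    keep = np.concatenate([[True], np.diff(t) > 0])
    return t[keep], v[keep]


def envelope_mean(x: Signal, boundary: str = "mirror") -> Signal | None:
    """Mean m(t) of the cubic-spline upper and lower extrema envelopes.

    Returns ``None`` when the signal has fewer than two maxima or two
    minima (the monotone-residue condition), signalling the caller to
    stop decomposing rather than raising.
    """
    s = x.samples
    maxima, minima = _local_extrema(s)
    if maxima.size < 2 or minima.size < 2:
        return None
    n = s.size
    t = np.arange(n, dtype=float)
    if boundary == "mirror":
        tmax, vmax = _mirrored_knots(maxima, s[maxima], n)
        tmin, vmin = _mirrored_knots(minima, s[minima], n)
    elif boundary == "none":
        tmax, vmax = maxima.astype(float), s[maxima]
        tmin, vmin = minima.astype(float), s[minima]
    else:
        raise ValueError(f"unknown boundary strategy: {boundary!r}")
    upper = CubicSpline(tmax, vmax)(t)
    lower = CubicSpline(tmin, vmin)(t)
    return Signal(0.5 * (upper + lower), x.fs)


def _counts_ok(s: np.ndarray) -> bool:
    maxima, minima = _local_extrema(s)
    return abs(maxima.size + minima.size - _zero_crossings(s)) <= 1


def is_imf(x: Signal, mean_tol: float = 0.1, boundary: str = "mirror") -> bool:
    """IMF test: extrema and zero-crossing counts differ by at most one,
    and the envelope mean is small relative to the signal amplitude."""
    s = x.samples
    if s.size < 4:
        return False
    maxima, minima = _local_extrema(s)
    n_ext = maxima.size + minima.size
    n_zc = _zero_crossings(s)
    if abs(n_ext - n_zc) > 1:
        return False
    m = envelope_mean(x, boundary)
    if m is None:
        return False
    amp = np.max(np.abs(s))
    if amp == 0:
        return False
    return bool(np.max(np.abs(m.samples)) <= mean_tol * amp)


def sd_criterion(h_prev: np.ndarray, h_curr: np.ndarray) -> float:
    """Sift stopping statistic: sum over t of |h_prev - h_curr|^2 / h_prev^2,
    with zero-denominator samples excluded."""
    h_prev = np.asarray(h_prev, dtype=float)
    h_curr = np.asarray(h_curr, dtype=float)
    if h_prev.shape != h_curr.shape:
        raise ValueError("h_prev and h_curr must have equal lengths")
    denom = h_prev**2
    keep = denom > 0
    if not np.any(keep):
        raise ValueError("h_prev is identically zero")
    num = (h_prev - h_curr) ** 2
    return float(np.sum(num[keep] / denom[keep]))


def sift(x: Signal, config: SiftingConfig | None = None) -> tuple[Signal, int]:
    """Extract one IMF by iterated envelope-mean subtraction.

    Iterates h <- h - m(h) until the IMF conditions hold and the SD
    criterion falls below ``sd_threshold``, or ``max_sift_iters`` is
    reached (in which case the iteration count is returned negated as a
    non-convergence flag).
    """
    config = config or SiftingConfig()
    fs = x.fs
    h = x.samples.copy()
    m = envelope_mean(Signal(h, fs), config.boundary)
    h_counts_ok = None  # latest iterate satisfying the extrema/crossing condition
    for it in range(1, config.max_sift_iters + 1):
        if m is None:
            return Signal(h, fs), it
        h_new = h - m.samples
        # inline IMF check, reusing the envelope of h_new for the next pass
        m_new = envelope_mean(Signal(h_new, fs), config.boundary)
        counts_ok = _counts_ok(h_new)
        if counts_ok:
            h_counts_ok = h_new
        imf_ok = counts_ok and m_new is not None
        if imf_ok:
            amp = np.max(np.abs(h_new))
            imf_ok = amp > 0 and np.max(np.abs(m_new.samples)) <= config.mean_tol * amp
        sd = sd_criterion(h, h_new) if np.any(h != 0) else 0.0
        if imf_ok and sd < config.sd_threshold:
            return Signal(h_new, fs), it
        h, m = h_new, m_new
    # cap reached: prefer the last iterate that at least satisfied the
    # oscillation-count condition; the negative count flags non-convergence
    if h_counts_ok is not None:
        return Signal(h_counts_ok, fs), -config.max_sift_iters
    return Signal(h, fs), -config.max_sift_iters


def _decomposable(s: np.ndarray, min_extrema: int) -> bool:
    maxima, minima = _local_extrema(s)
    return maxima.size >= min_extrema and minima.size >= min_extrema


def emd(x: Signal, config: SiftingConfig | None = None) -> IMFSet:
    """Full EMD: sift, subtract, recurse until the remainder is monotone
    (or nearly extremum-free). Residue is computed as the input minus the
    IMF sum, so reconstruction is exact."""
    config = config or SiftingConfig()
    imfs: list[Signal] = []
    counts: list[int] = []
    residue = x.samples.copy()
    while _decomposable(residue, config.min_extrema):
        if config.max_imfs and len(imfs) >= config.max_imfs:
            break
        c, it = sift(Signal(residue, x.fs), config)
        imfs.append(c)
        counts.append(it)
        residue = residue - c.samples
    return IMFSet(imfs=imfs, residue=Signal(residue, x.fs), sift_counts=counts, method="EMD")


def _pad_average(member_sets: list[IMFSet], fs: float, method: str, counts=None) -> IMFSet:
    n_max = max(len(m) for m in member_sets)
    n_samples = member_sets[0].residue.samples.size
    N = len(member_sets)
    acc = np.zeros((n_max, n_samples))
    res = np.zeros(n_samples)
    for m in member_sets:
        for i, c in enumerate(m.imfs):
            acc[i] += c.samples
        res += m.residue.samples
    acc /= N
    res /= N
    imfs = [Signal(acc[i], fs) for i in range(n_max)]
    return IMFSet(imfs=imfs, residue=Signal(res, fs), sift_counts=counts or [], method=method)


def eemd(x: Signal, sift_config: SiftingConfig | None = None,
         ens_config: EnsembleConfig | None = None) -> IMFSet:
    """Ensemble EMD: average index-aligned EMD modes of noise-perturbed
    copies of the signal. Members with fewer modes are zero-padded.
    With noise_amplitude 0 and ensemble size 1 this reduces to plain EMD."""
    sift_config = sift_config or SiftingConfig()
    ens_config = ens_config or EnsembleConfig()
    rng = np.random.default_rng(ens_config.seed)
    eps = ens_config.noise_amplitude * float(np.std(x.samples))
    members = []
    for _ in range(ens_config.ensemble_size):
        noise = eps * rng.standard_normal(x.samples.size) if eps > 0 else 0.0
        members.append(emd(Signal(x.samples + noise, x.fs), sift_config))
    if ens_config.ensemble_size == 1 and eps == 0.0:
        out = members[0]
        out.method = "EEMD"
        return out
    return _pad_average(members, x.fs, "EEMD")


def _first_mode(s: np.ndarray, fs: float, config: SiftingConfig) -> np.ndarray:
    """First sifted mode of s, or zeros when s is not decomposable."""
    if not _decomposable(s, config.min_extrema):
        return np.zeros_like(s)
    c, _ = sift(Signal(s, fs), config)
    return c.samples


def dema(x: Signal, sift_config: SiftingConfig | None = None,
         ens_config: EnsembleConfig | None = None) -> IMFSet:
    """Complete-ensemble adaptive-noise decomposition.

    Stage k averages, over the ensemble, the first sifted mode of the
    current residue perturbed by the k-th EMD mode of each stored noise
    realization; the perturbation amplitude adapts to the residue's
    standard deviation. The averaged mode is subtracted and the
    procedure recurses, so the IMFs plus the final residue reconstruct
    the input exactly for any seed and ensemble size. With
    noise_amplitude 0 and ensemble size 1 it coincides with plain EMD.
    """
    sift_config = sift_config or SiftingConfig()
    ens_config = ens_config or EnsembleConfig()
    n = x.samples.size
    eps0 = ens_config.noise_amplitude
    noise_free = eps0 == 0.0 and ens_config.ensemble_size == 1
    if noise_free:
        out = emd(x, sift_config)
        out.method = "DEMA"
        return out

    rng = np.random.default_rng(ens_config.seed)
    # stored noise realizations and their EMD mode banks
    noise_modes: list[np.ndarray] = []  # each (n_modes, n)
    for _ in range(ens_config.ensemble_size):
        w = rng.standard_normal(n)
        dec = emd(Signal(w, x.fs), sift_config)
        noise_modes.append(dec.as_matrix()[:-1] if len(dec) else np.zeros((0, n)))

    imfs: list[Signal] = []
    counts: list[int] = []
    residue = x.samples.copy()
    stage = 0
    while _decomposable(residue, sift_config.min_extrema):
        if sift_config.max_imfs and len(imfs) >= sift_config.max_imfs:
            break
        eps_k = eps0 * float(np.std(residue))
        acc = np.zeros(n)
        for bank in noise_modes:
            if stage < bank.shape[0] and eps_k > 0:
                mode = bank[stage]
                sd = float(np.std(mode))
                pert = residue + eps_k * (mode / sd if sd > 0 else mode)
            else:
                pert = residue
            acc += _first_mode(pert, x.fs, sift_config)
        c = acc / ens_config.ensemble_size
        if not np.any(c):
            break
        imfs.append(Signal(c, x.fs))
        counts.append(1)
        residue = residue - c
        stage += 1
    return IMFSet(imfs=imfs, residue=Signal(residue, x.fs), sift_counts=counts, method="DEMA")


def dominant_frequency(s: np.ndarray, fs: float) -> float:
    """Peak frequency of the (Hann-windowed, zero-padded) periodogram."""
    s = np.asarray(s, dtype=float)
    if s.size < 4 or not np.any(s - s.mean()):
        return 0.0
    nfft = int(2 ** np.ceil(np.log2(s.size * 4)))
    spec = np.abs(np.fft.rfft((s - s.mean()) * np.hanning(s.size), nfft)) ** 2
    f = np.fft.rfftfreq(nfft, 1.0 / fs)
    return float(f[np.argmax(spec)])


def band_partial(dec: IMFSet, lo: float, hi: float) -> Signal:
    """Sum of the IMFs whose dominant frequency falls inside [lo, hi] Hz
    — e.g. the cardiac-band (0.7-3 Hz) partial reconstruction."""
    fs = dec.residue.fs
    out = np.zeros_like(dec.residue.samples)
    for c in dec.imfs:
        if lo <= dominant_frequency(c.samples, fs) <= hi:
            out += c.samples
    return Signal(out, fs)


def _band_energy(s: np.ndarray, fs: float, lo: float, hi: float) -> float:
    spec = np.fft.rfft(s * np.hanning(s.size))
    f = np.fft.rfftfreq(s.size, 1.0 / fs)
    sel = (f >= lo) & (f <= hi)
    return float(np.sum(np.abs(spec[sel]) ** 2))


def mode_mixing_index(dec: IMFSet, reference: np.ndarray, band: tuple[float, float],
                      total: np.ndarray | None = None) -> float:
    """Fraction of a reference tone's band energy leaking outside its IMF.

    The IMF carrying the reference component is the one with the largest
    interior correlation against ``reference``; the index is the summed
    band energy of all *other* IMFs divided by the band energy of
    ``total`` (defaults to the reference itself). Zero means the tone is
    perfectly concentrated in a single mode; mode mixing spreads it.
    """
    fs = dec.residue.fs
    ref = np.asarray(reference, dtype=float)
    k = max(1, ref.size // 20)
    interior = slice(k, -k)

    def _corr(a: np.ndarray) -> float:
        ai = a[interior] - a[interior].mean()
        ri = ref[interior] - ref[interior].mean()
        denom = np.sqrt((ai @ ai) * (ri @ ri))
        return float(ai @ ri / denom) if denom > 0 else 0.0

    carrier = max(range(len(dec)), key=lambda i: _corr(dec.imfs[i].samples))
    denom = _band_energy(ref if total is None else np.asarray(total, float), fs, *band)
    outside = sum(
        _band_energy(c.samples, fs, *band) for i, c in enumerate(dec.imfs) if i != carrier
    )
    return outside / denom if denom > 0 else 0.0
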