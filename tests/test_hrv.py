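"""HRV features: autocorrelation, AR fitting, spectra, PCA."""
import numpy as np
import pytest
from scipy.linalg import solve_toeplitz

from bcgvitals.hrv import (
    ARSpectrum,
    ar_psd,
    autocorrelation,
    freq_domain_features,
    levinson_durbin,
    pca_reduce,
    resample_tachogram,
    time_domain_features,
    window_features,
)
from bcgvitals.rr import WindowedSample
from bcgvitals.synthetic import generate_ar_process


class TestAutocorrelation:
    def test_white_noise_lag1_small(self):
        x = np.random.default_rng(0).standard_normal(100_000)
        r = autocorrelation(x, 1)
        assert abs(r[1] / r[0]) < 0.02

    def test_ar1_decay(self):
        x = generate_ar_process([0.9], n=100_000, seed=1)
        r = autocorrelation(x, 5)
        np.testing.assert_allclose(r[1:] / r[0], 0.9 ** np.arange(1, 6), atol=0.02)

    def test_max_lag_too_large_raises(self):
        with pytest.raises(ValueError):
            autocorrelation(np.ones(10), 10)

    def test_constant_input_degenerates(self):
        r = autocorrelation(np.full(100, 5.0), 3)
        assert r[0] == 0.0
        with pytest.raises(ValueError):
            levinson_durbin(r, 2)


class TestLevinsonDurbin:
    def test_matches_direct_toeplitz_solve(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(200):
            x = rng.standard_normal(256)
            r = autocorrelation(x, 8)
            spec = levinson_durbin(r, 8)
            direct = solve_toeplitz((r[:8], r[:8]), r[1:9])
            worst = max(worst, float(np.max(np.abs(spec.coefficients - direct))))
        assert worst < 1e-8

    def test_exact_ar1_sequence_recovers_phi(self):
        r = 0.9 ** np.arange(17)
        spec = levinson_durbin(r, 16)
        assert abs(spec.coefficients[0] - 0.9) < 1e-10
        assert np.max(np.abs(spec.coefficients[1:])) < 1e-10

    def test_order_zero_noise_variance_is_r0(self):
        spec = levinson_durbin(np.array([2.5, 1.0]), order=0)
        assert spec.noise_variance == 2.5
        assert spec.coefficients.size == 0

    def test_reflection_coefficients_inside_unit_circle(self):
        x = generate_ar_process([0.5, -0.3], n=4000, seed=3)
        spec = levinson_durbin(autocorrelation(x, 16), 16)
        assert np.all(np.abs(spec.reflection_coeffs) < 1.0)

    def test_non_positive_definite_raises_naming_stage(self):
        r = np.array([1.0, 1.2, 0.0])
        with pytest.raises(ValueError, match="stage"):
            levinson_durbin(r, 2)


class TestArPsd:
    def test_order_zero_is_flat_noise_density(self):
        spec = ar_psd(ARSpectrum(0, np.empty(0), 3.0, np.empty(0)), fs=4.0)
        np.testing.assert_allclose(spec.psd, 3.0 / 4.0)

    def test_peak_at_pole_angle(self):
        radius, f_frac = 0.95, 0.1
        a = np.array([2 * radius * np.cos(2 * np.pi * f_frac), -(radius**2)])
        spec = ar_psd(ARSpectrum(2, a, 1.0, np.empty(0)), fs=1.0, n_freqs=512)
        grid_step = spec.freqs[1] - spec.freqs[0]
        assert abs(spec.freqs[np.argmax(spec.psd)] - f_frac) <= grid_step

    def test_parseval_recovers_process_variance(self):
        coeffs = np.array([0.4, -0.25, 0.1, 0.05])
        x = generate_ar_process(coeffs, n=20_000, seed=4)
        r = autocorrelation(x, 16)
        spec = ar_psd(levinson_durbin(r, 16), fs=1.0, n_freqs=4096)
        total = 2.0 * np.trapezoid(spec.psd, spec.freqs)
        assert abs(total - r[0]) / r[0] < 0.02


class TestTimeDomainFeatures:
    def test_constant_intervals(self):
        f = time_domain_features(WindowedSample(np.full(10, 1000.0), 0, 300))
        assert f.sdnn_ms == 0.0 and f.rmssd_ms == 0.0 and f.hr_bpm == 60.0

    def test_hand_computed_pair(self):
        f = time_domain_features(WindowedSample(np.array([800.0, 860.0]), 0, 300))
        assert f.rmssd_ms == 60.0
        assert f.pnn50_fraction == 1.0

    def test_alternating_intervals(self):
        iv = np.tile([780.0, 820.0], 50)
        f = time_domain_features(WindowedSample(iv, 0, 300))
        assert f.mean_rr_ms == 800.0
        assert f.hr_bpm == 75.0

    def test_single_interval_raises(self):
        with pytest.raises(ValueError):
            time_domain_features(WindowedSample(np.array([800.0]), 0, 300))


class TestFreqDomainFeatures:
    @staticmethod
    def _spec_for_modulation(f_mod):
        t = np.arange(0, 300, 0.25)
        tach = 800 + 40 * np.sin(2 * np.pi * f_mod * t)
        return levinson_durbin(autocorrelation(tach, 16), 16)

    def test_lf_modulation_dominates(self):
        fd = freq_domain_features(self._spec_for_modulation(0.1), 4.0)
        assert fd.lf_hf_ratio > 5.0

    def test_hf_modulation_dominates(self):
        fd = freq_domain_features(self._spec_for_modulation(0.25), 4.0)
        assert fd.hf_power > 5.0 * fd.lf_power

    def test_band_powers_bounded_by_total(self):
        spec = ar_psd(self._spec_for_modulation(0.1), 4.0)
        fd = freq_domain_features(spec, 4.0)
        total = 2.0 * np.trapezoid(spec.psd, spec.freqs)
        assert fd.vlf_power + fd.lf_power + fd.hf_power <= total * (1 + 1e-9)

    def test_window_features_combines_domains(self):
        rng = np.random.default_rng(0)
        iv = 800 + rng.normal(0, 25, 300)
        f = window_features(WindowedSample(iv, 0, 300))
        assert f.mean_rr_ms > 0 and f.lf_power >= 0 and f.hf_power >= 0

    def test_resample_needs_enough_intervals(self):
        with pytest.raises(ValueError):
            resample_tachogram(WindowedSample(np.array([800.0, 810.0]), 0, 300))


class TestPcaReduce:
    def test_rank_one_matrix_keeps_one_component(self):
        u = np.linspace(1, 2, 30)[:, None]
        v = np.array([[1.0, -0.5, 2.0]])
        reduced, red = pca_reduce(u @ v, standardize=False)
        assert red.n_kept == 1
        assert red.explained_variance_fractions[0] > 1 - 1e-9
        assert reduced.shape == (30, 1)

    def test_loadings_orthonormal(self):
        X = np.random.default_rng(3).standard_normal((40, 6))
        _, red = pca_reduce(X, variance_target=0.99)
        gram = red.components @ red.components.T
        np.testing.assert_allclose(gram, np.eye(red.n_kept), atol=1e-8)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((60, 5)) @ np.diag([3.0, 2.0, 1.0, 0.5, 0.1])
        _, red = pca_reduce(X, variance_target=0.999, standardize=False)
        C = np.cov((X - X.mean(0)).T)
        w, v = np.linalg.eigh(C)
        order = np.argsort(w)[::-1]
        for i in range(red.n_kept):
            dot = abs(red.components[i] @ v[:, order[i]])
            assert dot > 1 - 1e-8

    def test_zero_variance_matrix_raises(self):
        with pytest.raises(ValueError):
            pca_reduce(np.ones((10, 3)))
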