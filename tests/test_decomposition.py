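"""EMD sifting, ensemble averaging and the adaptive-noise variant."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcgvitals.core import Signal
from bcgvitals.decomposition import (
    EnsembleConfig,
    SiftingConfig,
    band_partial,
    dema,
    dominant_frequency,
    eemd,
    emd,
    envelope_mean,
    is_imf,
    sd_criterion,
    sift,
)
from tests.conftest import interior_corr


def _aligned_sine(fs=100.0, f=1.0, seconds=20.0):
    # extrema fall exactly on samples, so the spline envelopes are flat
    t = np.arange(0, seconds, 1 / fs)
    return Signal(np.sin(2 * np.pi * f * t), fs)


class TestEnvelopeMean:
    def test_sinusoid_interior_mean_near_zero(self):
        m = envelope_mean(_aligned_sine())
        assert np.max(np.abs(m.samples[200:-200])) < 0.01

    def test_offset_shifts_the_mean(self):
        x = _aligned_sine()
        m = envelope_mean(Signal(x.samples + 0.5, x.fs))
        assert np.allclose(m.samples[200:-200], 0.5, atol=0.01)

    def test_tracks_slow_component_under_fast_tone(self):
        t = np.arange(0, 20, 0.01)
        slow = np.sin(2 * np.pi * t)
        m = envelope_mean(Signal(slow + 0.5 * np.sin(10 * np.pi * t), 100.0))
        assert interior_corr(m.samples, slow) > 0.9

    def test_too_few_extrema_returns_none(self):
        assert envelope_mean(Signal(np.linspace(0, 1, 50), 1.0)) is None


class TestIsImf:
    def test_full_period_sine_is_imf(self):
        assert is_imf(_aligned_sine())

    def test_monotone_ramp_is_not(self):
        assert not is_imf(Signal(np.linspace(0, 1, 100), 1.0))

    def test_offset_sine_without_crossings_is_not(self):
        x = _aligned_sine()
        assert not is_imf(Signal(x.samples + 2.0, x.fs))


class TestSdCriterion:
    def test_identical_iterates_give_zero(self):
        h = np.sin(np.linspace(0, 10, 100))
        assert sd_criterion(h, h) == 0.0

    def test_hand_computed_five_sample_value(self):
        # zero-denominator sample excluded; others contribute 1 each
        h_prev = np.array([1.0, 2.0, 0.0, 4.0, 5.0])
        assert sd_criterion(h_prev, np.zeros(5)) == 4.0

    def test_all_zero_prev_raises(self):
        with pytest.raises(ValueError):
            sd_criterion(np.zeros(4), np.ones(4))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            sd_criterion(np.ones(4), np.ones(5))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_non_negative(self, seed):
        rng = np.random.default_rng(seed)
        h_prev = rng.standard_normal(32)
        h_curr = rng.standard_normal(32)
        assert sd_criterion(h_prev, h_curr) >= 0.0


class TestSift:
    def test_perfect_imf_is_a_fixed_point(self):
        x = _aligned_sine()
        h, iters = sift(x)
        assert iters == 1
        np.testing.assert_array_equal(h.samples, x.samples)

    def test_first_imf_of_two_tone_matches_fast_tone(self, two_tone):
        h, _ = sift(two_tone["signal"])
        assert interior_corr(h.samples, two_tone["fast"]) > 0.95


class TestEmd:
    def test_constant_signal_yields_no_imfs(self):
        x = Signal(np.full(100, 3.7), 10.0)
        dec = emd(x)
        assert len(dec) == 0
        np.testing.assert_array_equal(dec.residue.samples, x.samples)

    def test_reconstruction_identity(self, two_tone):
        dec = emd(two_tone["signal"])
        err = np.max(np.abs(dec.reconstruct() - two_tone["signal"].samples))
        assert err / np.max(np.abs(two_tone["signal"].samples)) < 1e-9

    def test_two_tone_plus_trend_separates(self, two_tone):
        dec = emd(two_tone["signal"])
        assert len(dec) == 2
        assert interior_corr(dec.imfs[0].samples, two_tone["fast"]) > 0.95
        assert interior_corr(dec.imfs[1].samples, two_tone["slow"]) > 0.95
        # residue carries the trend: near-perfect correlation and a net
        # rise matching the linear term (small oscillatory leftovers ok)
        assert interior_corr(dec.residue.samples, two_tone["trend"]) > 0.999
        interior = dec.residue.samples[200:-200]
        assert interior[-1] - interior[0] > 0.9 * (two_tone["trend"][-200] - two_tone["trend"][200])

    def test_zero_crossing_rate_decreases_across_imfs(self):
        rng = np.random.default_rng(0)
        dec = emd(Signal(rng.standard_normal(2048), 1.0))

        def zc(s):
            sg = np.sign(s)
            sg = sg[sg != 0]
            return int(np.count_nonzero(np.diff(sg)))

        rates = [zc(c.samples) for c in dec.imfs]
        assert all(a > b for a, b in zip(rates, rates[1:]))


class TestEemd:
    def test_noise_free_single_member_collapses_to_emd(self, two_tone):
        d0 = emd(two_tone["signal"])
        d1 = eemd(two_tone["signal"], None, EnsembleConfig(0.0, 1, 0))
        assert len(d0) == len(d1)
        for a, b in zip(d0.imfs, d1.imfs):
            np.testing.assert_array_equal(a.samples, b.samples)
        np.testing.assert_array_equal(d0.residue.samples, d1.residue.samples)

    def test_reconstruction_error_shrinks_with_ensemble_size(self):
        fs = 100.0
        t = np.arange(0, 10, 1 / fs)
        x = Signal(np.sin(2 * np.pi * t), fs)
        errs = []
        for n in (4, 16):
            dec = eemd(x, None, EnsembleConfig(0.2, n, seed=3))
            errs.append(np.sqrt(np.mean((dec.reconstruct() - x.samples) ** 2)))
        assert errs[1] < errs[0]


class TestDema:
    def test_noise_free_single_member_equals_emd(self, two_tone):
        d0 = emd(two_tone["signal"])
        d1 = dema(two_tone["signal"], None, EnsembleConfig(0.0, 1, 0))
        assert len(d0) == len(d1)
        for a, b in zip(d0.imfs, d1.imfs):
            np.testing.assert_array_equal(a.samples, b.samples)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_reconstruction_identity_any_seed(self, two_tone, seed):
        dec = dema(two_tone["signal"], None, EnsembleConfig(0.2, 4, seed))
        err = np.max(np.abs(dec.reconstruct() - two_tone["signal"].samples))
        assert err / np.max(np.abs(two_tone["signal"].samples)) < 1e-9

    def test_seeded_determinism(self, two_tone):
        a = dema(two_tone["signal"], None, EnsembleConfig(0.2, 4, 5))
        b = dema(two_tone["signal"], None, EnsembleConfig(0.2, 4, 5))
        assert len(a) == len(b)
        for ca, cb in zip(a.imfs, b.imfs):
            np.testing.assert_array_equal(ca.samples, cb.samples)


class TestBandHelpers:
    def test_dominant_frequency_of_tone(self):
        t = np.arange(0, 30, 0.01)
        assert abs(dominant_frequency(np.sin(2 * np.pi * 1.2 * t), 100.0) - 1.2) < 0.02

    def test_band_partial_selects_cardiac_imf(self, two_tone):
        dec = emd(two_tone["signal"])
        part = band_partial(dec, 0.7, 3.0)
        assert interior_corr(part.samples, two_tone["fast"]) > 0.95


def test_sifting_config_validation():
    with pytest.raises(ValueError):
        SiftingConfig(sd_threshold=0.0)
    with pytest.raises(ValueError):
        EnsembleConfig(ensemble_size=0)
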