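"""Empirical wavelet transform: boundaries, filter bank, decomposition."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ewtdoa.ewt import (
    BoundarySet,
    build_filter_bank,
    detect_boundaries,
    ewt_decompose,
    highest_band,
    max_gamma,
)

FS = 128.0
N = 56 * 128


def tone(freq_hz, n=N, fs=FS, amp=1.0):
    return amp * np.sin(2 * np.pi * freq_hz * np.arange(n) / fs)


class TestBoundaryDetection:
    def test_two_tone_boundary_lies_between_tones(self):
        x = tone(5.0) + tone(30.0)
        b = detect_boundaries(x, n_bands=2)
        lo, hi = 5.0 * 2 * np.pi / FS, 30.0 * 2 * np.pi / FS
        assert b.omegas.size == 1
        assert lo < b.omegas[0] < hi

    def test_two_tone_boundary_matches_direct_spectral_minimum(self):
        # oracle: locate the minimum of the magnitude spectrum between the
        # two FFT peaks by direct search
        x = tone(5.0, amp=2.0) + tone(30.0)
        mag = np.abs(np.fft.rfft(x))
        k1, k2 = round(5.0 * N / FS), round(30.0 * N / FS)
        k_min = k1 + 1 + np.argmin(np.log(mag + 1e-12)[k1 + 1 : k2])
        b = detect_boundaries(x, n_bands=2)
        assert b.omegas[0] == pytest.approx(2 * np.pi * k_min / N)

    def test_single_tone_triggers_fallback_with_warning(self, caplog):
        x = tone(10.0)
        with caplog.at_level(logging.WARNING, logger="ewtdoa.ewt"):
            b = detect_boundaries(x, n_bands=2)
        assert b.omegas.size == 1
        assert any("subdividing" in r.message for r in caplog.records)

    def test_white_noise_15_bands_monotone_boundaries(self, rng):
        x = rng.standard_normal(N)
        b = detect_boundaries(x, n_bands=15)
        assert b.omegas.size == 14
        assert np.all(np.diff(b.omegas) > 0)
        assert b.omegas[0] > 0 and b.omegas[-1] < np.pi

    def test_rejects_degenerate_requests(self, rng):
        with pytest.raises(ValueError):
            detect_boundaries(rng.standard_normal(64), n_bands=1)
        with pytest.raises(ValueError):
            detect_boundaries(rng.standard_normal(8), n_bands=8)


class TestFilterBank:
    def test_tight_frame_identity(self, rng):
        x = rng.standard_normal(N)
        bounds = detect_boundaries(x, n_bands=15)
        bank = build_filter_bank(bounds, n_samples=N)
        total = (bank.profiles**2).sum(axis=0)
        np.testing.assert_allclose(total, 1.0, atol=1e-10)

    def test_scaling_profile_meyer_edges(self):
        # oracle: the Meyer transition formula evaluated at the band edges
        bounds = BoundarySet(omegas=np.array([np.pi / 2]), n_bands=2)
        bank = build_filter_bank(bounds, gamma=0.1, n_samples=4096)
        w = 2 * np.pi * np.arange(4096 // 2 + 1) / 4096
        inner = w <= (1 - 0.1) * np.pi / 2
        outer = w >= (1 + 0.1) * np.pi / 2
        np.testing.assert_allclose(bank.scaling_hat[inner], 1.0, atol=1e-12)
        np.testing.assert_allclose(bank.scaling_hat[outer], 0.0, atol=1e-12)
        # at the boundary itself the raised cosine is at its half-way point
        k_b = round(np.pi / 2 / (2 * np.pi) * 4096)
        assert bank.scaling_hat[k_b] == pytest.approx(np.cos(np.pi / 4), abs=1e-6)

    def test_overlapping_transitions_rejected(self):
        bounds = BoundarySet(omegas=np.array([1.0, 1.1]), n_bands=3)
        with pytest.raises(ValueError, match="gamma"):
            build_filter_bank(bounds, gamma=0.9, n_samples=1024)

    def test_auto_gamma_below_feasible_maximum(self):
        bounds = BoundarySet(omegas=np.array([0.5, 1.0, 2.0]), n_bands=4)
        bank = build_filter_bank(bounds, n_samples=1024)
        assert 0 < bank.gamma < max_gamma(bounds)


class TestDecomposition:
    def test_perfect_reconstruction_random_window(self, rng):
        x = rng.standard_normal(N)
        dec = ewt_decompose(x, n_bands=15)
        err = np.linalg.norm(dec.reconstruct() - x) / np.linalg.norm(x)
        assert err < 1e-8

    def test_coefficient_energy_conservation(self, rng):
        x = rng.standard_normal(N)
        dec = ewt_decompose(x, n_bands=15)
        assert dec.band_energies().sum() == pytest.approx(
            (x**2).sum(), rel=1e-8
        )

    def test_two_tones_split_into_matching_bands(self):
        low, high = tone(5.0), tone(30.0)
        dec = ewt_decompose(low + high, n_bands=2)
        c0 = np.corrcoef(dec.subbands[0], low)[0, 1]
        c1 = np.corrcoef(dec.subbands[1], high)[0, 1]
        assert c0 > 0.99 and c1 > 0.99

    def test_zero_input_gives_zero_subbands(self):
        # a zero window has no spectral maxima at all: the fallback spacing
        # still yields a valid decomposition of all-zero bands
        dec = ewt_decompose(np.zeros(1024), n_bands=4)
        assert np.all(dec.subbands == 0) and np.all(dec.coeffs == 0)

    def test_highest_band_is_last_and_carries_high_tone(self):
        x = tone(5.0) + tone(50.0)
        dec = ewt_decompose(x, n_bands=2)
        band = highest_band(dec)
        assert np.shares_memory(band, dec.coeffs[-1])
        if dec.boundaries.omegas[-1] < 2 * np.pi * 50.0 / FS:
            energy_ratio = (band**2).sum() / (tone(50.0) ** 2).sum()
            assert energy_ratio >= 0.90

    def test_fifteen_band_indexing(self, rng):
        dec = ewt_decompose(rng.standard_normal(N), n_bands=15)
        np.testing.assert_array_equal(highest_band(dec), dec.coeffs[14])

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), n_bands=st.integers(2, 8))
    def test_reconstruction_and_monotone_boundaries_property(self, seed, n_bands):
        x = np.random.default_rng(seed).standard_normal(512)
        dec = ewt_decompose(x, n_bands=n_bands)
        assert np.all(np.diff(dec.boundaries.omegas) > 0)
        err = np.linalg.norm(dec.reconstruct() - x) / np.linalg.norm(x)
        assert err < 1e-8

    def test_band_table_covers_spectrum_and_total_energy(self, rng):
        from ewtdoa.ewt import band_table

        x = rng.standard_normal(1024)
        dec = ewt_decompose(x, n_bands=5)
        table = band_table(dec, fs=128.0, t_end=56.0)
        assert len(table) == 5
        assert table.low_hz.iloc[0] == 0.0 and table.high_hz.iloc[-1] == 64.0
        np.testing.assert_allclose(
            table.low_hz.iloc[1:].to_numpy(), table.high_hz.iloc[:-1].to_numpy()
        )
        assert table.energy.sum() == pytest.approx((x**2).sum(), rel=1e-10)

    def test_spectral_path_equals_time_domain_convolution(self, rng):
        # oracle: circular convolution with the inverse-transformed filters
        x = rng.standard_normal(64)
        dec = ewt_decompose(x, n_bands=3)
        xhat = np.fft.rfft(x)
        for k, profile in enumerate(dec.bank.profiles):
            h = np.fft.irfft(profile, n=64)
            direct = np.real(np.fft.ifft(np.fft.fft(x) * np.fft.fft(h)))
            np.testing.assert_allclose(dec.coeffs[k], direct, atol=1e-8)
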