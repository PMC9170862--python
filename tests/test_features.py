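"""Spectral entropy, SODP ellipse statistic and the per-window feature table."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from ewtdoa.features import (
    feature_table,
    sodp,
    sodp_components,
    spectral_entropy,
    window_features,
)
from ewtdoa.io import Window


def se_oracle(segment):
    """Brute-force oracle: direct DFT, power over positive bins, Shannon sum."""
    x = np.asarray(segment, dtype=float)
    n = len(x)
    n_pos = n // 2
    power = []
    for k in range(1, n_pos + 1):
        re = sum(x[j] * math.cos(-2 * math.pi * k * j / n) for j in range(n))
        im = sum(x[j] * math.sin(-2 * math.pi * k * j / n) for j in range(n))
        power.append(re * re + im * im)
    tot = sum(power)
    se = 0.0
    for p in power:
        p /= tot
        if p > 0:
            se -= p * math.log2(p)
    return se


def sodp_oracle(segment):
    """Step-by-step oracle for the ellipse statistic."""
    x = list(map(float, segment))
    X = [x[i + 1] - x[i] for i in range(len(x) - 1)]
    Xs, Ys = X[:-1], X[1:]
    n = len(Xs)
    sx2 = sum(v * v for v in Xs) / n
    sy2 = sum(v * v for v in Ys) / n
    sxy = sum(a * b for a, b in zip(Xs, Ys)) / n
    D = math.sqrt((sx2 + sy2) ** 2 - 4 * (sx2 * sy2 - sxy * sxy))
    area2 = (sx2 + sy2 + D) * (sx2 + sy2 - D)
    return abs(math.log(max(3 * math.pi * math.sqrt(max(area2, 0.0)), 1e-12)))


class TestSpectralEntropy:
    def test_flat_spectrum_reaches_log2_bins(self):
        # a unit impulse has perfectly flat spectral magnitude: entropy is
        # the log2 of the 64 positive-frequency bins of a 128-pt segment
        x = np.zeros(128)
        x[0] = 1.0
        assert spectral_entropy(x) == pytest.approx(6.0, abs=1e-10)

    def test_pure_on_bin_sinusoid_is_zero(self):
        t = np.arange(128)
        x = np.sin(2 * np.pi * 8 * t / 128)
        assert spectral_entropy(x) == pytest.approx(0.0, abs=1e-10)

    def test_matches_brute_force_oracle_on_fixture(self):
        seg = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0, 2.0, 4.0])
        assert spectral_entropy(seg) == pytest.approx(se_oracle(seg), abs=1e-10)

    def test_matches_oracle_on_random_segments(self, rng):
        for _ in range(25):
            seg = rng.standard_normal(rng.integers(4, 24))
            assert spectral_entropy(seg) == pytest.approx(
                se_oracle(seg), abs=1e-10
            )

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), scale=st.floats(1e-3, 1e3))
    def test_bounded_and_scale_invariant(self, seed, scale):
        seg = np.random.default_rng(seed).standard_normal(64)
        se = spectral_entropy(seg)
        assert 0.0 <= se <= np.log2(32) + 1e-12
        assert spectral_entropy(scale * seg) == pytest.approx(se, abs=1e-10)

    def test_all_zero_segment_yields_sentinel(self, caplog):
        with caplog.at_level("WARNING"):
            assert spectral_entropy(np.zeros(16)) == 0.0
        assert any("all-zero" in r.message for r in caplog.records)


class TestSODP:
    def test_constant_segment_hits_degenerate_floor(self, caplog):
        with caplog.at_level("WARNING"):
            val = sodp(np.array([5.0, 5.0, 5.0, 5.0]))
        assert val == pytest.approx(abs(math.log(1e-12)))
        assert any("degenerate" in r.message for r in caplog.records)

    def test_matches_literal_oracle_on_fixture(self):
        seg = [1.0, 3.0, 2.0, 5.0, 4.0, 6.0]
        assert sodp(seg) == pytest.approx(sodp_oracle(seg), abs=1e-10)

    def test_matches_oracle_on_random_segments(self, rng):
        for _ in range(100):
            seg = rng.standard_normal(128)
            assert sodp(seg) == pytest.approx(sodp_oracle(seg), abs=1e-10)

    def test_scaling_shifts_log_area(self, rng):
        seg = rng.standard_normal(128)
        assert sodp(10.0 * seg) == pytest.approx(
            sodp_oracle(10.0 * np.asarray(seg)), abs=1e-10
        )

    def test_components_ellipse_inequalities(self, rng):
        for _ in range(50):
            comp = sodp_components(rng.standard_normal(64))
            assert comp.SX >= 0 and comp.SY >= 0 and comp.D >= 0
            assert comp.D <= comp.SX**2 + comp.SY**2 + 1e-12

    def test_literal_radical_variant_differs_but_is_finite(self, rng):
        seg = 5.0 * rng.standard_normal(128)
        assert np.isfinite(sodp(seg, literal_radical=True))


class TestWindowFeatures:
    def test_identical_subsegments_average_to_single_value(self, rng):
        one_sec = rng.standard_normal(128)
        band = np.tile(one_sec, 56)
        wf = window_features(band, fs=128, t_end=56.0)
        assert wf.se_mean == pytest.approx(spectral_entropy(one_sec), abs=1e-10)
        assert wf.sodp_mean == pytest.approx(sodp(one_sec), abs=1e-10)
        assert wf.median_coeff == pytest.approx(np.median(band))

    def test_alternating_subsegments_average_to_midpoint(self, rng):
        a = rng.standard_normal(128)
        b = 3.0 * rng.standard_normal(128)
        band = np.concatenate([a, b] * 28)
        wf = window_features(band, fs=128, t_end=56.0)
        assert wf.se_mean == pytest.approx(
            (se_oracle(a) + se_oracle(b)) / 2, abs=1e-8
        )
        assert wf.sodp_mean == pytest.approx(
            (sodp_oracle(a) + sodp_oracle(b)) / 2, abs=1e-10
        )

    def test_white_noise_window_is_finite(self, rng):
        band = rng.standard_normal(56 * 128)
        wf = window_features(band, fs=128, t_end=56.0)
        assert np.isfinite([wf.se_mean, wf.sodp_mean, wf.median_coeff]).all()

    def test_partial_second_rejected(self, rng):
        with pytest.raises(ValueError, match="1-s segments"):
            window_features(rng.standard_normal(56 * 128 + 5), fs=128, t_end=56.0)


class TestFeatureTable:
    def _windows(self, rng, n=10):
        return [
            Window(samples=rng.standard_normal(56 * 128), t_end=56.0 + k)
            for k in range(n)
        ]

    def test_cardinality_preserved(self, rng):
        wins = self._windows(rng)
        table = feature_table(wins, fs=128, n_bands=4)
        assert len(table) == len(wins)
        np.testing.assert_array_equal(
            table["t_end"], [w.t_end for w in wins]
        )

    def test_ref_absent_when_no_track(self, rng):
        table = feature_table(self._windows(rng, 4), fs=128, n_bands=4)
        assert table["ref_value"].isna().all()

    def test_ref_aligned_to_window_end(self, rng):
        ref = np.arange(70, dtype=float)  # value at second k+1 is k
        table = feature_table(
            self._windows(rng, 4), fs=128, n_bands=4, ref_index=ref
        )
        np.testing.assert_array_equal(table["ref_value"], [55, 56, 57, 58])

    def test_deterministic(self, rng):
        wins = self._windows(rng, 5)
        t1 = feature_table(wins, fs=128, n_bands=4)
        t2 = feature_table(wins, fs=128, n_bands=4)
        assert t1.equals(t2)


class TestDepthEncodingMonotonicity:
    def test_se_rises_with_high_frequency_fraction(self, rng):
        # the property the depth mapping relies on: as the high-frequency
        # fraction of a 1/f^alpha noise mixture grows (alpha falls), the
        # highest subband's mean spectral entropy rises monotonically
        from ewtdoa.ewt import ewt_decompose, highest_band

        n = 56 * 128
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white)
        f = np.maximum(np.fft.rfftfreq(n, d=1 / 128.0), 0.5)
        alphas = np.linspace(3.0, 0.5, 20)
        ses = []
        for alpha in alphas:
            x = np.fft.irfft(spec * f ** (-alpha / 2.0), n=n)
            band = highest_band(ewt_decompose(x, n_bands=15))
            ses.append(window_features(band, 128, 56.0).se_mean)
        rho = spearmanr(-alphas, ses).statistic
        assert rho > 0.9
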