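import numpy as np
import pytest

from skewatlas import signal_analysis as sig
from skewatlas.properties import PropertyTrack
from skewatlas.signal_analysis import (
    CondensedVector, autocorrelation, condense, confidence_interval,
    cross_correlation, denoise, find_peak, haar_reverse_cumulative_similarity,
    imodwt, modwt, pairwise_cross_correlations, similarity_summary,
)

from .conftest import brute_force_acf, brute_force_ccf


def _track(values, window=1000):
    starts = [1 + window * i for i in range(len(values))]
    return PropertyTrack.from_values("t", "s", window, window, starts, list(values))


def _vec(values, bin_width=1.0):
    values = np.asarray(values, dtype=float)
    return CondensedVector(values=values, m=int(np.log2(values.size)), bin_width=bin_width)


class TestCondense:
    def test_exact_halving(self):
        vals = np.arange(4096, dtype=float)
        x = condense(_track(vals), 11)
        assert x.n == 2048
        expected = vals.reshape(2048, 2).mean(axis=1)
        np.testing.assert_allclose(x.values, expected, atol=1e-9)

    def test_constant_track_stays_constant(self):
        x = condense(_track([3.5] * 100), 6)
        np.testing.assert_allclose(x.values, 3.5)

    def test_matches_brute_force_overlap_weighted_oracle(self):
        rng = np.random.default_rng(11)
        n_windows, window = 3000, 1000
        vals = rng.normal(size=n_windows)
        track = _track(vals, window=window)
        x = condense(track, 11)
        # O(windows x bins) oracle: bp overlap of every window with every bin
        L = n_windows * window
        n_bins = 2048
        width = L / n_bins
        w_lo = np.arange(n_windows)[:, None] * window
        w_hi = w_lo + window
        b_lo = np.arange(n_bins)[None, :] * width
        b_hi = b_lo + width
        overlap = np.clip(np.minimum(w_hi, b_hi) - np.maximum(w_lo, b_lo), 0.0, None)
        oracle = (overlap * vals[:, None]).sum(axis=0) / overlap.sum(axis=0)
        np.testing.assert_allclose(x.values, oracle, atol=1e-12)

    def test_invariants_and_errors(self):
        x = condense(_track(np.arange(100.0)), 5)
        assert x.bin_width == pytest.approx(100_000 / 32)
        with pytest.raises(ValueError):
            condense(_track([1.0, 2.0]), 0)


class TestModwt:
    def test_constant_vector_all_detail_free(self):
        x = np.full(64, 2.5)
        w = modwt(x, "haar", J=3)
        for d in w.details:
            np.testing.assert_allclose(d, 0.0, atol=1e-12)
        np.testing.assert_allclose(w.smooth, x, atol=1e-12)
        np.testing.assert_allclose(w.denoised, x, atol=1e-12)

    def test_haar_level1_detail_is_half_difference(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=256)
        w = modwt(x, "haar", J=2)
        expected = (x - np.roll(x, 1)) / 2.0
        np.testing.assert_allclose(w.details[0], expected, atol=1e-12)

    @pytest.mark.parametrize("filter_name", sig.SUPPORTED_FILTERS)
    @pytest.mark.parametrize("n", [64, 256, 2048])
    def test_perfect_reconstruction_and_energy(self, filter_name, n):
        rng = np.random.default_rng(42)
        x = rng.normal(size=n)
        J = 4
        w = modwt(x, filter_name, J=J)
        assert all(d.size == n for d in w.details) and w.smooth.size == n
        energy = sum(float(d @ d) for d in w.details) + float(w.smooth @ w.smooth)
        assert energy == pytest.approx(float(x @ x), rel=1e-8)
        np.testing.assert_allclose(imodwt(w), x, atol=1e-10)

    def test_unsupported_filter_lists_supported(self):
        with pytest.raises(ValueError, match="haar"):
            modwt(np.arange(8.0), "morlet", J=1)

    def test_level_beyond_log2_rejected(self):
        with pytest.raises(ValueError, match="J"):
            modwt(np.arange(8.0), "haar", J=4)


class TestDenoise:
    def test_smooth_lambda_shape_preserved(self):
        n = 512
        lam = np.concatenate([np.arange(n // 2), n // 2 - np.arange(n // 2)]).astype(float)
        rng = np.random.default_rng(1)
        noisy = lam + rng.normal(0, 0.5, size=n)
        den = denoise(noisy, "haar", J=4)
        assert np.corrcoef(den, noisy)[0, 1] >= 0.99

    def test_white_noise_variance_shrinks(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=512)
        assert denoise(x, "haar", J=4).var() < x.var()

    def test_level_zero_disallowed(self):
        with pytest.raises(ValueError):
            denoise(np.arange(16.0), "haar", J=0)


class TestConfidenceInterval:
    def test_published_values(self):
        assert confidence_interval(2048, 0.999) == pytest.approx(0.073, abs=5e-4)
        assert confidence_interval(1, 0.95) == pytest.approx(1.96, abs=5e-3)

    @pytest.mark.parametrize("p, z", [(0.95, 1.96), (0.99, 2.58), (0.999, 3.29)])
    def test_normal_critical_values(self, p, z):
        assert confidence_interval(1, p) == pytest.approx(z, abs=5e-3)

    def test_monotonic_in_n_and_p(self):
        ns = [16, 64, 256, 1024]
        cis = [confidence_interval(n, 0.99) for n in ns]
        assert all(a > b for a, b in zip(cis, cis[1:]))
        ps = [0.9, 0.95, 0.99, 0.999]
        cis = [confidence_interval(256, p) for p in ps]
        assert all(a < b for a, b in zip(cis, cis[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            confidence_interval(256, 1.5)
        with pytest.raises(ValueError):
            confidence_interval(0, 0.95)


class TestAutocorrelation:
    def test_lag_zero_is_one_and_range(self):
        rng = np.random.default_rng(3)
        acf = autocorrelation(rng.normal(size=128))
        assert acf.coefficients[0] == pytest.approx(1.0)
        assert acf.lags.tolist() == list(range(128))
        assert np.all(np.abs(acf.coefficients) <= 1.0 + 1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=200)
        acf = autocorrelation(x)
        np.testing.assert_allclose(acf.coefficients, brute_force_acf(x), atol=1e-10)

    def test_cosine_peaks_at_period_multiples(self):
        n, period = 512, 64
        x = np.cos(2 * np.pi * np.arange(n) / period)
        acf = autocorrelation(x)
        mags = acf.coefficients
        for lag in (period, 2 * period, 3 * period):
            assert mags[lag] > mags[lag - period // 2]
            # closed form: r(k) ~ (1 - k/n) cos(2 pi k / period), so the local
            # maximum sits within a bin or two of each period multiple
            window = slice(lag - 8, lag + 9)
            assert abs(int(np.argmax(mags[window])) + lag - 8 - lag) <= 2

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            autocorrelation(np.full(32, 1.0))


class TestCrossCorrelation:
    def test_self_correlation_at_lag_zero(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=64)
        ccf = cross_correlation(x, x)
        assert ccf.coefficients[63] == pytest.approx(1.0)
        assert ccf.lags.tolist() == list(range(-63, 64))

    def test_periodic_shift_peaks_at_shift_lag(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=256)
        for s in (5, 31):
            peak = find_peak(cross_correlation(x, np.roll(x, s)))
            assert abs(peak.lag_bins) == s

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=150), rng.normal(size=150)
        ccf = cross_correlation(x, y)
        np.testing.assert_allclose(ccf.coefficients, brute_force_ccf(x, y), atol=1e-10)

    def test_argument_swap_reverses_lags(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=100), rng.normal(size=100)
        np.testing.assert_allclose(
            cross_correlation(x, y).coefficients,
            cross_correlation(y, x).coefficients[::-1],
            atol=1e-12,
        )

    def test_errors(self):
        with pytest.raises(ValueError, match="sizes differ"):
            cross_correlation(np.arange(8.0), np.arange(16.0))
        with pytest.raises(ValueError, match="zero-variance"):
            cross_correlation(np.full(16, 1.0), np.arange(16.0))


class TestFindPeak:
    def test_triangle_peak_matches_brute_force_scan(self):
        """The strongest |r| local extremum of a Lambda vector, by exhaustive scan."""
        n = 256
        tri = np.concatenate([np.arange(n // 2), n // 2 - np.arange(n // 2)]).astype(float)
        acf = autocorrelation(tri)
        r = brute_force_acf(tri)
        mags = np.abs(r)
        local = [
            k for k in range(1, n - 1)
            if mags[k] > mags[k - 1] and mags[k] > mags[k + 1]
        ]
        expected = max(local, key=lambda k: (mags[k], -k))
        peak = find_peak(acf)
        assert peak.lag_bins == expected
        assert peak.coefficient < 0
        # the half-length coefficient is exactly -0.5 under the biased taper
        assert r[n // 2] == pytest.approx(-0.5, abs=1e-12)

    def test_white_noise_peak_rarely_significant(self):
        n = 256
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(1000 + seed).normal(size=n)
            peak = find_peak(autocorrelation(x, p=0.999))
            hits += not peak.significant
        assert hits >= 95

    def test_injected_extremum_is_found(self):
        r = np.zeros(64)
        r[0] = 1.0
        r[40] = 0.8
        series = sig.CorrelationSeries(
            kind="auto", lags=np.arange(64), coefficients=r, N=64,
            confidence_level=0.999, ci=confidence_interval(64, 0.999),
        )
        peak = find_peak(series)
        assert peak.lag_bins == 40
        assert peak.significant

    def test_monotone_series_flagged_not_significant(self):
        r = np.linspace(1.0, 0.0, 32)
        series = sig.CorrelationSeries(
            kind="auto", lags=np.arange(32), coefficients=r, N=32,
            confidence_level=0.999, ci=0.5,
        )
        peak = find_peak(series)
        assert not peak.significant
        assert peak.lag_bins == 1  # global max-|r| in range

    def test_lag_bp_uses_bin_width(self):
        x = np.cos(2 * np.pi * np.arange(128) / 16)
        vec = _vec(x, bin_width=250.0)
        peak = find_peak(autocorrelation(vec))
        assert peak.lag_bp == pytest.approx(peak.lag_bins * 250.0)


class TestSimilaritySummary:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(9)
        x = _vec(rng.normal(size=256))
        assert similarity_summary(x, x) == pytest.approx(1.0, abs=1e-9)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=256)
        b = rng.normal(size=256) + 0.3 * a
        s1 = similarity_summary(_vec(a), _vec(b))
        s2 = similarity_summary(_vec(2.0 * a + 7.0), _vec(b))
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_independent_noise_pairs_score_low(self):
        scores = []
        for seed in range(20):
            rng = np.random.default_rng(500 + seed)
            scores.append(
                similarity_summary(_vec(rng.normal(size=2048)), _vec(rng.normal(size=2048)))
            )
        assert np.mean(scores) < 0.2

    def test_periodic_shift_scores_high(self):
        rng = np.random.default_rng(12)
        x = np.cumsum(rng.normal(size=2048))  # smooth signal
        y = np.roll(x, 64)
        score = similarity_summary(_vec(x), _vec(y))
        assert score >= 0.9


class TestHaarReverseCumulative:
    @pytest.mark.parametrize("J", [1, 4])
    def test_noisy_skew_fixture_high_correlation(self, noisy_skew_track, J):
        x = condense(noisy_skew_track, 7)
        assert haar_reverse_cumulative_similarity(x, J=J) >= 0.9

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            haar_reverse_cumulative_similarity(np.full(64, 1.0), J=1)


def test_pairwise_analysis_count_is_k_choose_2():
    rng = np.random.default_rng(13)
    vectors = {f"t{i}": _vec(rng.normal(size=64)) for i in range(4)}
    results = pairwise_cross_correlations(vectors)
    assert len(results) == 6  # 4*3/2
    assert all(a != b for a, b in results)
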