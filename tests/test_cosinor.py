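"""Harmonic regression, Fourier scoring, AR(1) null machinery."""
import numpy as np
import pytest

from dielcycle.cosinor import (Cosinor24, cycling_pvalue, design_matrix,
                               fit_ar1, fit_ar1_pooled, fit_sinusoid_24h,
                               simulate_null_scores)
from dielcycle.simulate import ar1_noise


def cosine(times, m, H, phase):
    return m + H * np.cos(2 * np.pi * (times - phase) / 24.0)


class TestFit:
    def test_noise_free_identity(self, times):
        res = fit_sinusoid_24h(times, cosine(times, 2.0, 1.0, 6.0))
        assert res.mesor == pytest.approx(2.0, abs=1e-9)
        assert res.halfamp == pytest.approx(1.0, abs=1e-9)
        assert res.phase == pytest.approx(6.0, abs=1e-9)
        assert res.fold_change == pytest.approx(4.0, abs=1e-8)

    def test_constant_series_flat_fit(self, times):
        res = fit_sinusoid_24h(times, np.full(len(times), 5.0))
        assert res.halfamp == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(res.phase)
        assert res.fourier_score == pytest.approx(0.0, abs=1e-12)

    def test_phase_wraps_into_period(self, times):
        res = fit_sinusoid_24h(times, cosine(times, 0.0, 1.0, 23.5))
        assert res.phase == pytest.approx(23.5, abs=1e-9)

    def test_matches_grid_search_oracle(self, times):
        # brute force: for each candidate phase, LS over (mesor, amplitude)
        rng = np.random.default_rng(3)
        phases = np.arange(0, 24, 0.01)
        cosg = np.cos(2 * np.pi * (times[None, :] - phases[:, None]) / 24.0)
        for _ in range(20):
            y = cosine(times, rng.normal(), rng.uniform(0.3, 2.0),
                       rng.uniform(0, 24)) + rng.normal(0, 0.3, len(times))
            best = (np.inf, None, None)
            for i in range(len(phases)):
                X = np.column_stack([np.ones_like(times), cosg[i]])
                coef, res_, *_ = np.linalg.lstsq(X, y, rcond=None)
                sse = ((y - X @ coef) ** 2).sum()
                if coef[1] >= 0 and sse < best[0]:
                    best = (sse, phases[i], coef[1])
            fit = fit_sinusoid_24h(times, y)
            dphi = abs(fit.phase - best[1])
            assert min(dphi, 24 - dphi) <= 0.05
            assert fit.halfamp == pytest.approx(best[2], abs=0.005)

    def test_summary_mentions_phase_and_amplitude(self, times):
        text = fit_sinusoid_24h(times, cosine(times, 0, 1, 3)).summary()
        assert "half-amplitude" in text and "phase" in text

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            Cosinor24([0, 2, 4], [1, 2, 3])

    def test_short_span_rejected(self):
        with pytest.raises(ValueError, match="half a period"):
            Cosinor24([0, 2, 4, 6, 8], [1, 2, 3, 2, 1])


def test_fourier_score_matches_dft_on_even_window():
    # one full period evenly sampled: harmonic OLS == DFT component
    t = np.arange(0, 24, 2.0)
    rng = np.random.default_rng(1)
    y = rng.normal(0, 1, len(t))
    res = fit_sinusoid_24h(t, y)
    dft = np.fft.rfft(y)[1]          # 24-h component for a 24-h window
    assert res.fourier_score == pytest.approx(2 * abs(dft) / len(t), abs=1e-9)


class TestAr1Fit:
    def test_white_noise_phi_near_zero(self):
        rng = np.random.default_rng(0)
        phi, sd = fit_ar1(rng.normal(0, 1, 10_000))
        assert phi == pytest.approx(0.0, abs=0.02)
        assert sd == pytest.approx(1.0, rel=0.05)

    def test_recovers_generating_phi(self):
        rng = np.random.default_rng(1)
        phi, sd = fit_ar1(ar1_noise(rng, 10_000, 0.6, 1.0))
        assert phi == pytest.approx(0.6, abs=0.02)
        assert sd == pytest.approx(1.0, rel=0.05)

    def test_constant_series_degenerate_null(self, times):
        phi, sd = fit_ar1(np.full(14, 3.0))
        assert (phi, sd) == (0.0, 0.0)
        null = simulate_null_scores(phi, sd, times, 500, np.random.default_rng(0))
        assert (null == 0).all()
        assert cycling_pvalue(0.5, null) == pytest.approx(1 / 501)

    def test_pooled_estimator_recovers_cohort_parameters(self, times):
        rng = np.random.default_rng(2)
        series = []
        for _ in range(300):
            y = ar1_noise(rng, 14, 0.3, 0.25) + rng.uniform(0.0, 1.5) * np.cos(
                2 * np.pi * (times - rng.uniform(0, 24)) / 24.0)
            series.append((times, y))
        phi, sd = fit_ar1_pooled(series)
        assert phi == pytest.approx(0.3, abs=0.08)
        assert sd == pytest.approx(0.25, abs=0.02)

    def test_pooled_estimator_empty_degenerate(self):
        assert fit_ar1_pooled([]) == (0.0, 0.0)


class TestNullScores:
    def test_deterministic_given_seed(self, times):
        a = simulate_null_scores(0.3, 0.25, times, 1000, np.random.default_rng(5))
        b = simulate_null_scores(0.3, 0.25, times, 1000, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_zero_innovation_all_zero(self, times):
        null = simulate_null_scores(0.5, 0.0, times, 200, np.random.default_rng(0))
        assert (null == 0).all()

    def test_score_scale_equivariance(self, times):
        # doubling the innovation sd doubles every null score distributionally
        a = simulate_null_scores(0.3, 0.25, times, 2000, np.random.default_rng(7))
        b = simulate_null_scores(0.3, 0.50, times, 2000, np.random.default_rng(7))
        np.testing.assert_allclose(b, 2 * a, rtol=1e-10)


class TestPvalue:
    def test_exceeds_all_nulls(self):
        assert cycling_pvalue(10.0, np.zeros(1000)) == pytest.approx(1 / 1001)

    def test_below_all_nulls(self):
        assert cycling_pvalue(0.0, np.ones(1000)) == 1.0

    def test_at_empirical_median(self):
        null = np.arange(1, 1002, dtype=float)  # 1001 scores, median 501
        p = cycling_pvalue(501.0, null)
        assert p == pytest.approx(0.5, abs=1 / 1001)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            cycling_pvalue(1.0, [])


def test_design_matrix_columns(times):
    X = design_matrix(times)
    assert X.shape == (len(times), 3)
    np.testing.assert_allclose(X[:, 0], 1.0)
    np.testing.assert_allclose(X[:, 1] ** 2 + X[:, 2] ** 2, 1.0)


def test_weighted_fit_downweights_outlier(times):
    y = cosine(times, 0.0, 1.0, 6.0)
    y[3] += 5.0
    w = np.ones(len(times))
    w[3] = 1e-9
    res = Cosinor24(times, y, weights=w).fit()
    assert res.phase == pytest.approx(6.0, abs=0.05)
    assert res.halfamp == pytest.approx(1.0, abs=0.05)
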