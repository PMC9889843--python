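"""Cosinor fitting, rhythmicity testing and phase/R2/SNR arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from circadiff import (
    fit_cosinor,
    r2_from_snr,
    rhythm_test,
    snr_from_r2,
    wrap_phase_diff,
)
from circadiff.cosinor import gaussian_loglik

from conftest import cosine
from _oracles import grid_search_cosinor


class TestFitCosinor:
    def test_noise_free_reconstruction(self, even24):
        y = cosine(even24, 2.0, 6.0, 10.0)
        f = fit_cosinor(y, even24)
        assert f.amplitude == pytest.approx(2.0, abs=1e-9)
        assert f.phase == pytest.approx(6.0, abs=1e-9)
        assert f.mesor == pytest.approx(10.0, abs=1e-9)
        assert f.r2 == pytest.approx(1.0, abs=1e-9)
        assert f.degenerate

    def test_flat_signal_convention(self, even24):
        f = fit_cosinor(np.full(24, 5.0), even24)
        assert f.amplitude == pytest.approx(0.0, abs=1e-12)
        assert f.mesor == pytest.approx(5.0)
        assert f.r2 == 0.0
        assert f.phase == 0.0
        assert f.degenerate
        assert f.p_rhythm == 1.0

    def test_matches_grid_search_oracle(self, noisy_gene):
        y, t = noisy_gene
        f = fit_cosinor(y, t)
        A, phi, M = grid_search_cosinor(y, t)
        assert f.amplitude == pytest.approx(A, abs=1e-3)
        assert f.phase == pytest.approx(phi, abs=1e-3)
        assert f.mesor == pytest.approx(M, abs=1e-3)

    def test_matches_statsmodels_ols(self, noisy_gene):
        import statsmodels.api as sm

        y, t = noisy_gene
        f = fit_cosinor(y, t)
        w = 2 * np.pi / 24
        X = sm.add_constant(np.column_stack([np.sin(w * t), np.cos(w * t)]))
        res = sm.OLS(y, X).fit()
        assert f.mesor == pytest.approx(res.params[0], abs=1e-10)
        assert f.a == pytest.approx(res.params[1], abs=1e-10)
        assert f.b == pytest.approx(res.params[2], abs=1e-10)
        assert f.r2 == pytest.approx(res.rsquared, abs=1e-10)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            fit_cosinor([1, 2, 3, 4], [0, 6, 12, 18])

    def test_degenerate_time_design_rejected(self, even24):
        t = np.full(24, 3.0)
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_cosinor(np.arange(24.0), t)
        # all times congruent mod the period is equally degenerate
        t = np.tile([5.0], 24) + 24.0 * np.arange(24)
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_cosinor(np.arange(24.0), t)

    @given(
        A=st.floats(0.1, 10),
        phi=st.floats(0, 23.999),
        M=st.floats(-50, 50),
    )
    def test_ab_amplitude_phase_bijection(self, A, phi, M):
        """(a, b) <-> (A, phi) is an exact bijection for A > 0."""
        w = 2 * math.pi / 24
        a = A * math.sin(w * phi)
        b = A * math.cos(w * phi)
        A2 = math.hypot(a, b)
        phi2 = math.atan2(a, b) / w % 24
        assert A2 == pytest.approx(A, rel=1e-10)
        assert min(abs(phi2 - phi), 24 - abs(phi2 - phi)) < 1e-8

    @given(shift=st.floats(-48, 48))
    def test_time_translation_equivariance(self, shift, noisy_gene):
        y, t = noisy_gene
        f0 = fit_cosinor(y, t)
        f1 = fit_cosinor(y, t + shift)
        assert f1.amplitude == pytest.approx(f0.amplitude, abs=1e-9)
        assert f1.mesor == pytest.approx(f0.mesor, abs=1e-9)
        assert f1.sigma == pytest.approx(f0.sigma, abs=1e-9)
        assert f1.r2 == pytest.approx(f0.r2, abs=1e-9)
        assert f1.loglik == pytest.approx(f0.loglik, abs=1e-7)
        expected_phase = (f0.phase + shift) % 24
        assert min(abs(f1.phase - expected_phase),
                   24 - abs(f1.phase - expected_phase)) < 1e-8

    @given(c=st.floats(0.1, 10), d=st.floats(-20, 20))
    def test_affine_equivariance(self, c, d, noisy_gene):
        y, t = noisy_gene
        f0 = fit_cosinor(y, t)
        f1 = fit_cosinor(c * y + d, t)
        assert f1.amplitude == pytest.approx(c * f0.amplitude, rel=1e-8)
        assert f1.sigma == pytest.approx(c * f0.sigma, rel=1e-8)
        assert f1.mesor == pytest.approx(c * f0.mesor + d, rel=1e-8, abs=1e-8)
        assert f1.r2 == pytest.approx(f0.r2, abs=1e-9)


class TestRhythmTest:
    def test_perfect_rhythm_degenerate_branch(self, even24):
        y = cosine(even24, 2.0, 6.0, 10.0)
        stat, df, p = rhythm_test(y, even24)
        assert math.isinf(stat)
        assert p == 0.0

    def test_lrt_equals_twice_loglik_difference(self, noisy_gene):
        """LRT statistic recomputed from the two likelihood formulas."""
        y, t = noisy_gene
        stat, df, p = rhythm_test(y, t, method="LRT")
        f = fit_cosinor(y, t)
        rss0 = float(np.sum((y - y.mean()) ** 2))
        ll_null = gaussian_loglik(rss0, y.size)
        assert stat == pytest.approx(2 * (f.loglik - ll_null), abs=1e-9)
        assert df == 2
        assert p == pytest.approx(stats.chi2.sf(stat, 2))

    def test_f_statistic_matches_anova_form(self, noisy_gene):
        y, t = noisy_gene
        stat, (df1, df2), p = rhythm_test(y, t, method="F")
        f = fit_cosinor(y, t)
        n = y.size
        rss1 = f.sigma**2 * n
        rss0 = float(np.sum((y - y.mean()) ** 2))
        expected = ((rss0 - rss1) / 2) / (rss1 / (n - 3))
        assert stat == pytest.approx(expected, rel=1e-9)
        assert (df1, df2) == (2, n - 3)

    def test_null_calibration_and_uniformity(self, even24):
        """F-test p-values are exact under the Gaussian null; the LRT is
        allowed mild small-sample anticonservatism."""
        rng = np.random.default_rng(77)
        n_reps = 2000
        p_f = np.empty(n_reps)
        p_lrt = np.empty(n_reps)
        for i in range(n_reps):
            y = rng.normal(0, 1, 24)
            _, _, p_f[i] = rhythm_test(y, even24, method="F")
            _, _, p_lrt[i] = rhythm_test(y, even24, method="LRT")
        rate_f = np.mean(p_f <= 0.05)
        half = 2.576 * math.sqrt(0.05 * 0.95 / n_reps)
        assert abs(rate_f - 0.05) <= half
        assert abs(np.mean(p_lrt <= 0.05) - 0.05) <= 0.03
        assert stats.kstest(p_f, "uniform").pvalue > 0.01


class TestPhaseWrap:
    @pytest.mark.parametrize(
        "phi_ref, phi_cmp, expected",
        [
            (11.3, 3.5, -7.8),  # reference peaks late, comparison early
            (23.0, 1.0, 2.0),  # wrap across midnight
            (6.0, 18.0, 12.0),  # antipodal boundary maps to +P/2
            (0.0, 0.0, 0.0),
        ],
    )
    def test_examples(self, phi_ref, phi_cmp, expected):
        assert wrap_phase_diff(phi_ref, phi_cmp) == pytest.approx(expected)

    @given(a=st.floats(-100, 100), b=st.floats(-100, 100))
    def test_range_and_antisymmetry(self, a, b):
        d = wrap_phase_diff(a, b)
        assert -12.0 < d <= 12.0
        if abs(d) != 12.0:
            assert wrap_phase_diff(b, a) == pytest.approx(-d, abs=1e-9)


class TestR2Snr:
    def test_anchor_values(self):
        assert r2_from_snr(0.0) == 0.0
        assert r2_from_snr(math.sqrt(2)) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            r2_from_snr(-0.1)

    @given(snr=st.floats(0, 50))
    def test_monotone_and_round_trip(self, snr):
        r2 = r2_from_snr(snr)
        assert 0.0 <= r2 < 1.0
        assert r2_from_snr(snr + 0.1) > r2
        assert snr_from_r2(r2) == pytest.approx(snr, abs=1e-12, rel=1e-12)

    def test_large_n_empirical_r2(self):
        """Empirical R^2 of a big fit matches snr^2/(snr^2+2) (snr=1)."""
        rng = np.random.default_rng(5)
        n = 10000
        t = rng.uniform(0, 24, n)
        y = cosine(t, 2.0, 6.0, 0.0) + rng.normal(0, 2.0, n)
        f = fit_cosinor(y, t)
        assert f.r2 == pytest.approx(1.0 / 3.0, abs=0.01)
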