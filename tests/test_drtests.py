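"""Differential rhythmicity tests: nulls, oracles, symmetries, gating."""

import math

import numpy as np
import pytest
from scipy import stats

from circadiff import (
    GroupParams,
    SimScenario,
    calibration_experiment,
    fitness_test,
    global_param_test,
    posthoc_param_test,
)
from circadiff.drtests import bartlett_factor

from conftest import cosine
from _oracles import (
    fitness_constrained_grid,
    global_constrained_grid,
    shared_amplitude_grid,
    shared_mesor_grid,
    shared_phase_profile_grid,
)


@pytest.fixture(scope="module")
def toy_pair():
    """A 20-sample-per-group toy instance with distinct group parameters."""
    rng = np.random.default_rng(11)
    t = np.arange(20) * 1.2
    y_I = cosine(t, 2.0, 6.0, 10.0) + rng.normal(0, 1.0, 20)
    y_II = cosine(t, 1.2, 9.0, 11.0) + rng.normal(0, 0.8, 20)
    return y_I, t, y_II, t


class TestFitnessTest:
    def test_identical_groups_are_exact_null(self, noisy_gene):
        y, t = noisy_gene
        r = fitness_test(y, t, y, t)
        assert r.delta_snr == 0.0
        assert r.delta_r2 == 0.0
        assert r.lrt_stat <= 1e-6
        assert r.p_value > 0.99

    def test_constrained_mle_matches_grid_oracle(self, toy_pair):
        r = fitness_test(*toy_pair)
        # reconstruct the constrained loglik from the reported statistic
        from circadiff import fit_cosinor

        y_I, t_I, y_II, t_II = toy_pair
        ll_free = fit_cosinor(y_I, t_I).loglik + fit_cosinor(y_II, t_II).loglik
        ll_con = ll_free - r.lrt_stat / 2
        ll_grid = fitness_constrained_grid(*toy_pair)
        assert ll_con == pytest.approx(ll_grid, abs=1e-4)

    def test_group_swap_symmetry(self, toy_pair):
        y_I, t_I, y_II, t_II = toy_pair
        r = fitness_test(y_I, t_I, y_II, t_II)
        s = fitness_test(y_II, t_II, y_I, t_I)
        assert s.delta_snr == pytest.approx(-r.delta_snr, abs=1e-9)
        assert s.delta_r2 == pytest.approx(-r.delta_r2, abs=1e-9)
        assert s.lrt_stat == pytest.approx(r.lrt_stat, abs=1e-6)
        assert s.p_value == pytest.approx(r.p_value, abs=1e-6)

    def test_affine_invariance(self, toy_pair):
        y_I, t_I, y_II, t_II = toy_pair
        r = fitness_test(y_I, t_I, y_II, t_II)
        s = fitness_test(3 * y_I + 7, t_I, 3 * y_II + 7, t_II)
        assert s.lrt_stat == pytest.approx(r.lrt_stat, abs=1e-6)
        assert s.delta_snr == pytest.approx(r.delta_snr, abs=1e-9)

    def test_zero_noise_vs_arrhythmic(self, even24):
        y_rhy = cosine(even24, 2.0, 3.0, 10.0)
        rng = np.random.default_rng(0)
        y_flat = 10.0 + rng.normal(0, 1, 24)
        r = fitness_test(y_rhy, even24, y_flat, even24)
        assert r.p_value == 0.0
        assert r.flag == "degenerate"

    def test_null_pvalues_uniform(self):
        sc = SimScenario(group_i=GroupParams(2, 6, 10, 1.0),
                         group_ii=GroupParams(1, 2, 5, 0.5),
                         n_per_group=24)
        r = calibration_experiment("fitness", sc, n_reps=1000, seed=31)
        assert stats.kstest(r.p_values, "uniform").pvalue > 0.01


class TestGlobalParamTest:
    def test_identical_groups_are_exact_null(self, noisy_gene):
        y, t = noisy_gene
        for params in (("phase", "amplitude"), ("phase", "amplitude", "mesor")):
            g = global_param_test(y, t, y, t, params=params)
            assert g.stat <= 1e-6
            assert g.p_value > 0.99

    @pytest.mark.parametrize("share_mesor", [False, True])
    def test_constrained_mle_matches_grid_oracle(self, toy_pair, share_mesor):
        params = ("phase", "amplitude", "mesor") if share_mesor else (
            "phase", "amplitude")
        g = global_param_test(*toy_pair, params=params)
        from circadiff import fit_cosinor

        y_I, t_I, y_II, t_II = toy_pair
        ll_free = fit_cosinor(y_I, t_I).loglik + fit_cosinor(y_II, t_II).loglik
        ll_con = ll_free - g.stat / 2
        ll_grid = global_constrained_grid(*toy_pair, share_mesor=share_mesor,
                                          halfwidth=1.0, step=0.004)
        assert ll_con >= ll_grid - 1e-4
        assert ll_con == pytest.approx(ll_grid, abs=5e-3)

    def test_df_by_parameter_set(self, toy_pair):
        assert global_param_test(*toy_pair).df == 2
        assert global_param_test(
            *toy_pair, params=("phase", "amplitude", "mesor")).df == 3

    def test_invalid_params_rejected(self, toy_pair):
        with pytest.raises(ValueError, match="params"):
            global_param_test(*toy_pair, params=("amplitude",))

    def test_null_pvalues_uniform(self):
        sc = SimScenario(group_i=GroupParams(2, 6, 10, 1.0),
                         group_ii=GroupParams(2, 6, 12, 2.0),
                         n_per_group=24)
        r = calibration_experiment("global_phiA", sc, n_reps=1000, seed=32)
        assert stats.kstest(r.p_values, "uniform").pvalue > 0.01


class TestPosthocTests:
    def test_noise_free_phase_shift(self, even24):
        y_I = cosine(even24, 2.0, 3.0, 10.0)
        y_II = cosine(even24, 2.0, 9.0, 10.0)
        r = posthoc_param_test(y_I, even24, y_II, even24, param="phase")
        assert r.delta == pytest.approx(6.0, abs=1e-9)
        assert r.p_value == 0.0

    def test_phase_profile_matches_grid(self, toy_pair):
        r = posthoc_param_test(*toy_pair, param="phase")
        from circadiff import fit_cosinor

        y_I, t_I, y_II, t_II = toy_pair
        ll_free = fit_cosinor(y_I, t_I).loglik + fit_cosinor(y_II, t_II).loglik
        ll_con = ll_free - r.stat / 2
        phi_grid, ll_grid = shared_phase_profile_grid(*toy_pair, step=0.001)
        assert ll_con == pytest.approx(ll_grid, abs=1e-4)

    def test_amplitude_and_mesor_match_grids(self, toy_pair):
        y_I, t_I, y_II, t_II = toy_pair
        from circadiff import fit_cosinor

        ll_free = fit_cosinor(y_I, t_I).loglik + fit_cosinor(y_II, t_II).loglik
        r_amp = posthoc_param_test(*toy_pair, param="amplitude")
        assert ll_free - r_amp.stat / 2 == pytest.approx(
            shared_amplitude_grid(*toy_pair), abs=1e-4
        )
        r_m = posthoc_param_test(*toy_pair, param="mesor")
        assert ll_free - r_m.stat / 2 == pytest.approx(
            shared_mesor_grid(*toy_pair), abs=1e-4
        )

    def test_deltas_follow_ii_minus_i(self, toy_pair):
        y_I, t_I, y_II, t_II = toy_pair
        from circadiff import fit_cosinor

        fI = fit_cosinor(y_I, t_I)
        fII = fit_cosinor(y_II, t_II)
        assert posthoc_param_test(*toy_pair, param="amplitude").delta == \
            pytest.approx(fII.amplitude - fI.amplitude)
        assert posthoc_param_test(*toy_pair, param="mesor").delta == \
            pytest.approx(fII.mesor - fI.mesor)

    def test_unknown_param(self, toy_pair):
        with pytest.raises(ValueError, match="unknown parameter"):
            posthoc_param_test(*toy_pair, param="frequency")

    @pytest.mark.parametrize("which", ["posthoc_phase", "posthoc_amplitude",
                                       "posthoc_mesor"])
    def test_null_pvalues_uniform(self, which):
        sc = SimScenario(group_i=GroupParams(2, 6, 10, 1.0),
                         group_ii=GroupParams(2, 6, 10, 1.5),
                         n_per_group=24)
        r = calibration_experiment(which, sc, n_reps=1000, seed=33)
        assert stats.kstest(r.p_values, "uniform").pvalue > 0.01


class TestBartlettFactor:
    def test_matches_digamma_identity(self):
        from scipy.special import digamma

        n, q = 48, 2
        expected = n * (digamma(22.0) - digamma(21.0)) / q
        assert bartlett_factor(n, q) == pytest.approx(expected)
        assert bartlett_factor(n, q) == pytest.approx(48 / 21 / 2)

    def test_approaches_one_for_large_n(self):
        assert bartlett_factor(100000, 3) == pytest.approx(1.0, abs=1e-3)


def test_all_lrt_statistics_nonnegative(toy_pair):
    rng = np.random.default_rng(9)
    t = np.arange(24.0)
    for _ in range(25):
        y_I = cosine(t, 1.5, rng.uniform(0, 24), 8.0) + rng.normal(0, 1, 24)
        y_II = cosine(t, 1.5, rng.uniform(0, 24), 8.0) + rng.normal(0, 1, 24)
        assert fitness_test(y_I, t, y_II, t).lrt_stat >= -1e-6
        assert global_param_test(y_I, t, y_II, t).stat >= -1e-6
        for param in ("phase", "amplitude", "mesor"):
            assert posthoc_param_test(y_I, t, y_II, t, param=param).stat >= -1e-6
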