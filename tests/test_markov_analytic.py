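"""Master equation and phase-type shutoff statistics."""

import math

import numpy as np
import pytest

from rhodeact import markov_analytic as ma
from rhodeact.scheme import FAST, SLOW, DynamicsPreset, build_scheme


class TestSolveMaster:
    def test_initial_condition_is_unit_mass_on_state_one(self, wt_slow,
                                                         grid_3s):
        prob = ma.solve_master(wt_slow, grid_3s)
        assert prob.P[0, 0] == 1.0
        assert np.all(prob.P[1:, 0] == 0.0)

    def test_probability_conserved_to_1e9_over_30s(self, wt_slow):
        grid = np.linspace(0.0, 30.0, 3001)
        prob = ma.solve_master(wt_slow, grid)
        np.testing.assert_allclose(prob.P.sum(axis=0), 1.0, atol=1e-9)
        assert np.all(prob.P >= -1e-12) and np.all(prob.P <= 1 + 1e-12)

    def test_two_state_toy_matches_closed_form(self, toy_two_state):
        # lam1 = mu2 = 1: P1(t) = e^-t, P2(t) = t e^-t, P3 = 1 - (1+t) e^-t
        grid = np.linspace(0.0, 5.0, 501)
        prob = ma.solve_master(toy_two_state, grid)
        np.testing.assert_allclose(prob.P[0], np.exp(-grid), atol=1e-8)
        np.testing.assert_allclose(prob.P[1], grid * np.exp(-grid), atol=1e-8)
        np.testing.assert_allclose(prob.P[2],
                                   1 - (1 + grid) * np.exp(-grid), atol=1e-8)

    def test_ode_solver_agrees_with_exponential_propagation(self, wt_slow):
        grid = np.linspace(0.0, 1.0, 101)
        p_expm = ma.solve_master(wt_slow, grid, method="expm")
        p_ode = ma.solve_master(wt_slow, grid, method="ode")
        np.testing.assert_allclose(p_ode.P, p_expm.P, atol=1e-6)

    def test_arrestin_ko_accumulates_in_terminal_active_state(self,
                                                             arrko_slow):
        grid = np.array([0.0, 5.0])
        prob = ma.solve_master(arrko_slow, grid)
        assert prob.P[6, -1] > 0.999          # fully phosphorylated, active
        assert prob.P[7, -1] < 1e-12          # inactive state never reached

    def test_rejects_non_monotone_grid(self, wt_slow):
        with pytest.raises(ValueError):
            ma.solve_master(wt_slow, np.array([0.0, 2.0, 1.0]))
        with pytest.raises(ValueError):
            ma.solve_master(wt_slow, np.array([0.5, 1.0]))


class TestStepDistribution:
    def test_wt_slow_pmf_matches_direct_evaluation(self, wt_slow):
        dist = ma.step_distribution(wt_slow)
        np.testing.assert_allclose(dist.pmf[3:],
                                   [0.6557, 0.2550, 0.0760, 0.0133],
                                   atol=5e-5)
        assert np.all(dist.pmf[:3] == 0.0)
        assert dist.deficit == pytest.approx(0.0, abs=1e-12)

    def test_pmf_plus_deficit_is_one(self, wt_slow, p3_slow, arrko_slow):
        for scheme in (wt_slow, p3_slow, arrko_slow):
            dist = ma.step_distribution(scheme)
            assert dist.pmf.sum() + dist.deficit == pytest.approx(1.0,
                                                                  abs=1e-12)

    def test_three_site_mutant_shuts_off_deterministically_in_four_steps(
            self, p3_slow):
        dist = ma.step_distribution(p3_slow)
        assert dist.pmf[3] == pytest.approx(1.0)
        assert ma.mean_steps(p3_slow) == pytest.approx(4.0)

    @pytest.mark.parametrize("n_sites", [0, 1, 2])
    def test_too_few_sites_never_shut_off(self, n_sites):
        dist = ma.step_distribution(build_scheme(n_sites, SLOW))
        assert dist.deficit == pytest.approx(1.0)
        with pytest.raises(ma.NoShutoffError):
            dist.mean()

    def test_arrestin_ko_never_shuts_off(self, arrko_slow):
        assert ma.step_distribution(arrko_slow).deficit == pytest.approx(1.0)

    @pytest.mark.parametrize("preset,expected", [(SLOW, 4.45), (FAST, 4.41)])
    def test_wt_mean_steps_matches_printed_value(self, preset, expected):
        assert ma.mean_steps(build_scheme(6, preset)) == pytest.approx(
            expected, abs=5e-3)


class TestExpectedLifetime:
    @pytest.mark.parametrize("preset,expected_ms", [(SLOW, 75.0),
                                                    (FAST, 41.0)])
    def test_wt_lifetime_matches_printed_value(self, preset, expected_ms):
        t = ma.expected_lifetime(build_scheme(6, preset))
        assert t * 1e3 == pytest.approx(expected_ms, abs=0.5)

    def test_wt_lifetime_within_1pct_of_preset_target(self):
        for preset in (SLOW, FAST):
            t = ma.expected_lifetime(build_scheme(6, preset))
            assert t == pytest.approx(preset.tau_R_target, rel=0.01)

    def test_three_site_lifetime_is_sum_of_sojourns(self, p3_slow):
        # all four states visited with probability 1
        assert ma.expected_lifetime(p3_slow) * 1e3 == pytest.approx(
            31.75 + 47.62 + 95.24 + 16.67, abs=0.02)

    @pytest.mark.parametrize("n_sites", [0, 1, 2])
    def test_no_shutoff_genotypes_live_forever(self, n_sites):
        assert math.isinf(ma.expected_lifetime(build_scheme(n_sites, SLOW)))


class TestTheoreticalCV:
    @pytest.mark.parametrize("n_sites,expected",
                             [(3, 0.56), (4, 0.54), (5, 0.52), (6, 0.51)])
    def test_printed_theoretical_row(self, n_sites, expected):
        cv = ma.theoretical_cv_total_activity(build_scheme(n_sites, SLOW))
        assert cv == pytest.approx(expected, abs=5e-3)

    def test_single_state_cv_is_one(self, toy_two_state):
        # restricting the sum to one state collapses the formula to 1
        assert ma.theoretical_cv_total_activity(
            toy_two_state, n_steps=1) == pytest.approx(1.0)

    def test_invalid_for_no_shutoff_schemes(self, arrko_slow):
        with pytest.raises(ma.NoShutoffError):
            ma.theoretical_cv_total_activity(arrko_slow)
        with pytest.raises(ma.NoShutoffError):
            ma.theoretical_cv_total_activity(build_scheme(2, SLOW))

    def test_invariant_under_nu_and_time_rescaling(self, wt_slow):
        base = ma.theoretical_cv_total_activity(wt_slow)
        for c in (7.0, 0.2):
            scaled_nu = DynamicsPreset("s", 10.5, 60.0, 330.0 * c, 0.5, 0.075)
            scaled_t = DynamicsPreset("t", 10.5 * c, 60.0 * c, 330.0, 0.5,
                                      0.075 / c)
            assert ma.theoretical_cv_total_activity(
                build_scheme(6, scaled_nu)) == pytest.approx(base, rel=1e-12)
            assert ma.theoretical_cv_total_activity(
                build_scheme(6, scaled_t)) == pytest.approx(base, rel=1e-12)


class TestTotalActivity:
    def test_per_state_products_match_printed_row(self, wt_slow):
        np.testing.assert_allclose(
            ma.activity_products(wt_slow),
            [5.24, 3.81, 2.89, 0.80, 0.55, 0.38, 0.27], atol=7e-3)

    def test_aggregate_equals_visit_weighted_sum(self, wt_slow):
        v = ma.visit_probabilities(wt_slow)
        prod = ma.activity_products(wt_slow)
        assert ma.total_expected_activations(wt_slow) == pytest.approx(
            float((v * prod).sum()))
        assert ma.total_expected_activations(wt_slow) == pytest.approx(
            12.97, abs=0.02)

    def test_aggregate_matches_monte_carlo_mean(self, wt_slow):
        # oracle: sampled mean of sum nu_k T_k over complete paths
        rng = np.random.default_rng(7)
        dist = ma.step_distribution(wt_slow)
        tau = 1.0 / wt_slow.total_rates
        n = 200_000
        m = rng.choice(dist.support, size=n, p=dist.pmf / dist.pmf.sum())
        T = rng.exponential(tau, size=(n, 7))
        T *= np.arange(1, 8)[None, :] <= m[:, None]
        t_tot = T @ wt_slow.nu
        se = t_tot.std(ddof=1) / math.sqrt(n)
        assert abs(t_tot.mean() - ma.total_expected_activations(wt_slow)) \
            < 3 * se

    def test_linear_in_nu(self, wt_slow):
        scaled = DynamicsPreset("s", 10.5, 60.0, 330.0 * 3, 0.5, 0.075)
        assert ma.total_expected_activations(
            build_scheme(6, scaled)) == pytest.approx(
                3 * ma.total_expected_activations(wt_slow))

    def test_integrated_mean_activity_identity(self, wt_slow):
        # integral over [0, inf) of sum nu_k P_k(t) equals the mean total
        # integrated activity.  Exact route: occupancy-time integrals solve
        # the linear system -(Q_active)^T o = p0, independent of the
        # product-form visit probabilities used by the implementation.
        from scipy.linalg import solve
        Q = ma.generator_matrix(wt_slow)[:7, :7]
        p0 = np.zeros(7)
        p0[0] = 1.0
        occupancy = solve(-Q.T, p0)
        assert float(wt_slow.nu @ occupancy) == pytest.approx(
            ma.total_expected_activations(wt_slow), rel=1e-6)
        # and the master-equation quadrature agrees to grid accuracy
        grid = np.linspace(0.0, 30.0, 30001)
        act = ma.mean_activity(ma.solve_master(wt_slow, grid))
        assert np.trapezoid(act, grid) == pytest.approx(
            ma.total_expected_activations(wt_slow), rel=1e-3)


class TestExpectedActivity:
    def test_constant_nu_gives_that_constant(self):
        preset = DynamicsPreset("c", 10.5, 60.0, 42.0, 0.0, 0.075)
        est, se = ma.expected_activity(build_scheme(6, preset),
                                       n_paths=20_000, seed=3)
        assert est == pytest.approx(42.0, abs=1e-9)

    def test_monte_carlo_reproducible_and_near_first_moment_ratio(self,
                                                                  wt_slow):
        est1, se1 = ma.expected_activity(wt_slow, n_paths=100_000, seed=11)
        est2, _ = ma.expected_activity(wt_slow, n_paths=100_000, seed=11)
        assert est1 == est2
        ratio, _ = ma.expected_activity(wt_slow, method="ratio_of_means")
        assert ratio == pytest.approx(172.0, abs=1.0)
        # expectation of the ratio sits near, but not exactly at, the
        # ratio of expectations
        assert abs(est1 - ratio) / ratio < 0.25
        assert se1 < 1.0

    def test_requires_certain_shutoff(self, arrko_slow):
        with pytest.raises(ma.NoShutoffError):
            ma.expected_activity(arrko_slow, n_paths=100)
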