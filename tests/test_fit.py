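"""Likelihood, saturated model, ML fitting and the nested LR test."""

import numpy as np
import pytest
from scipy.stats import chi2

from cncb import (
    ConfidenceParams,
    RatingCounts,
    SimulationDesign,
    calibrate_boundaries,
    fit_cncb,
    log_likelihood,
    lr_test,
    saturated_log_likelihood,
    simulate_dataset,
)
from cncb.model import response_probabilities


def _counts_from_probs(sens, conf, n_per_stim=200_000):
    """Deterministic 'expected-count' table: counts proportional to the
    exact model probabilities (rounded)."""
    p = response_probabilities(sens, conf).p
    n = np.round(p * n_per_stim).astype(np.int64)
    return RatingCounts(n=n, mu=sens.mu)


class TestLogLikelihood:
    def test_hand_computed_toy_table(self, default_sens, default_conf):
        # n over the 4 cells of each stimulus: compare against plain
        # sum n log p evaluated by hand from the model table
        p = response_probabilities(default_sens, default_conf).p
        n = np.array([[[3, 2], [5, 0]], [[0, 1], [4, 7]]], dtype=np.int64)
        counts = RatingCounts(n=n, mu=default_sens.mu)
        by_hand = sum(
            n[i, j, k] * np.log(p[i, j, k])
            for i in range(2) for j in range(2) for k in range(2)
            if n[i, j, k] > 0
        )
        assert log_likelihood(default_sens, default_conf, counts) == \
            pytest.approx(by_hand, abs=1e-10)

    def test_bounded_by_saturated(self, default_sens, default_conf):
        rng = np.random.default_rng(2)
        n = rng.integers(0, 50, size=(2, 2, 2))
        n[0, 0, 0] += 1  # ensure nonzero rows
        n[1, 0, 0] += 1
        counts = RatingCounts(n=n.astype(np.int64), mu=default_sens.mu)
        assert log_likelihood(default_sens, default_conf, counts) <= \
            saturated_log_likelihood(counts)

    def test_saturated_attained_at_model_frequencies(self, default_sens,
                                                     default_conf):
        counts = _counts_from_probs(default_sens, default_conf, 10_000_000)
        gap = saturated_log_likelihood(counts) - \
            log_likelihood(default_sens, default_conf, counts)
        assert 0 <= gap < 0.01  # only rounding error remains


class TestSaturatedLogLikelihood:
    def test_single_cell_per_stimulus_is_zero(self):
        n = np.zeros((2, 2, 2), dtype=np.int64)
        n[0, 1, 1] = 17
        n[1, 0, 0] = 9
        counts = RatingCounts(n=n, mu=np.array([-1.0, 1.0]))
        assert saturated_log_likelihood(counts) == 0.0

    def test_uniform_counts(self):
        n = np.full((1, 2, 2), 2, dtype=np.int64)
        n = np.concatenate([n, n])  # two stimuli, 4 cells of 2, N_i = 8
        counts = RatingCounts(n=n, mu=np.array([-1.0, 1.0]))
        assert saturated_log_likelihood(counts) == \
            pytest.approx(16 * np.log(0.25))

    def test_equals_multinomial_maximum(self):
        # direct maximization oracle: maximize sum n log q over the simplex
        # by scipy for a random table
        from scipy.optimize import minimize

        rng = np.random.default_rng(4)
        n = rng.integers(1, 30, size=(1, 2, 3)).astype(np.int64)
        counts = RatingCounts(n=np.vstack([n, n]), mu=np.array([-1.0, 1.0]))
        flat = n.ravel().astype(float)

        def neg(qlogit):
            q = np.exp(qlogit)
            q = q / q.sum()
            return -np.sum(flat * np.log(q))

        res = minimize(neg, np.zeros(flat.size), method="Nelder-Mead",
                       options={"fatol": 1e-12, "xatol": 1e-9,
                                "maxiter": 20000})
        assert saturated_log_likelihood(counts) == \
            pytest.approx(-2 * res.fun, abs=1e-5)


class TestFitCNCB:
    def test_recovers_generating_parameters(self, six_strength_sens):
        b = calibrate_boundaries(six_strength_sens, 0.5, 0.2, [0.25] * 4)
        conf = ConfidenceParams(0.5, 0.2, b)
        design = SimulationDesign(n_trials=10_000, n_levels=4, seed=42)
        _, counts = simulate_dataset(six_strength_sens, conf, design)
        fit = fit_cncb(counts)
        assert fit.converged
        assert fit.sens.sigma_s == pytest.approx(1.0, abs=0.1)
        assert fit.sens.theta_s == pytest.approx(0.0, abs=0.1)
        assert fit.conf.sigma_c == pytest.approx(0.5, abs=0.3)
        assert fit.conf.alpha == pytest.approx(0.2, abs=0.25)
        assert fit.deviance == pytest.approx(
            -2 * (fit.logL - fit.logL_saturated), abs=1e-6)
        assert fit.deviance >= 0

    def test_exact_probabilities_recover_exactly(self, default_sens):
        # expected counts from the model itself: the optimum is the truth
        b = calibrate_boundaries(default_sens, 0.8, 0.0, [0.25] * 4)
        conf = ConfidenceParams(0.8, 0.0, b)
        counts = _counts_from_probs(default_sens, conf, 2_000_000)
        fit = fit_cncb(counts, "no_boost")
        assert fit.conf.sigma_c == pytest.approx(0.8, abs=0.02)
        assert fit.sens.sigma_s == pytest.approx(1.0, abs=0.02)
        np.testing.assert_allclose(fit.conf.boundaries, b, atol=0.03)

    def test_nesting_no_boost_inside_with_boost(self, default_sens):
        b = calibrate_boundaries(default_sens, 0.7, 0.0, [0.25] * 4)
        conf = ConfidenceParams(0.7, 0.0, b)
        design = SimulationDesign(n_trials=10_000, n_levels=4, seed=5)
        _, counts = simulate_dataset(default_sens, conf, design)
        fit0 = fit_cncb(counts, "no_boost")
        fit1 = fit_cncb(counts, "with_boost")
        # within optimizer precision along the flat (sigma_c, alpha) ridge
        assert fit1.logL >= fit0.logL - 1e-3
        lam, p = lr_test(fit0, fit1)
        assert lam <= chi2.ppf(0.999, 1)  # no spurious huge improvement

    def test_fix_sensory_option(self, default_sens):
        b = calibrate_boundaries(default_sens, 0.5, 0.2, [0.25] * 4)
        conf = ConfidenceParams(0.5, 0.2, b)
        design = SimulationDesign(n_trials=10_000, n_levels=4, seed=8)
        _, counts = simulate_dataset(default_sens, conf, design)
        fit = fit_cncb(counts, fix_sensory=(1.0, 0.0))
        assert fit.sens.sigma_s == 1.0 and fit.sens.theta_s == 0.0
        assert fit.n_free_params == 3 + 2  # sigma_c, alpha, 3 boundaries

    def test_likelihood_invariant_to_stimulus_relabeling(self, default_sens,
                                                         default_conf):
        rng = np.random.default_rng(0)
        n = rng.integers(1, 100, size=(2, 2, 2)).astype(np.int64)
        counts = RatingCounts(n=n, mu=default_sens.mu)
        # mirror the whole problem (stimulus signs and decisions flipped):
        # in the unbiased symmetric design this relabels the stimuli, and
        # the likelihood must not change
        mirrored = RatingCounts(n=n[::-1, ::-1, :].copy(), mu=default_sens.mu)
        assert log_likelihood(default_sens, default_conf, counts) == \
            pytest.approx(
                log_likelihood(default_sens, default_conf, mirrored),
                abs=1e-9)

    def test_deviance_distribution_matches_chi_square(self, default_sens):
        # well-specified model: G^2 ~ chi2 with df = (#cells - 1 per
        # stimulus summed) - #free params
        b = calibrate_boundaries(default_sens, 0.5, 0.2, [0.25] * 4)
        conf = ConfidenceParams(0.5, 0.2, b)
        devs = []
        for seed in range(30):
            design = SimulationDesign(n_trials=4_000, n_levels=4, seed=seed)
            _, counts = simulate_dataset(default_sens, conf, design)
            devs.append(fit_cncb(counts).deviance)
        df = 2 * (8 - 1) - (2 + 2 + 3)
        mean_dev = np.mean(devs)
        se = np.sqrt(2 * df / len(devs))
        assert abs(mean_dev - df) < 4 * se


class TestLRTest:
    def test_identical_likelihoods(self, default_sens):
        b = np.array([0.3, 0.8, 1.3])
        conf = ConfidenceParams(0.5, 0.0, b)
        counts = _counts_from_probs(default_sens, conf, 10_000)
        import dataclasses

        fit0 = fit_cncb(counts, "no_boost", options={"polish": False,
                                                     "nm_maxiter": 50})
        res = dataclasses.replace(fit0, model_variant="with_boost")
        lam, p = lr_test(fit0, res)
        assert lam == 0.0 and p == 1.0

    def test_chi_square_quantile(self):
        assert chi2.sf(3.841, 1) == pytest.approx(0.05, abs=1e-3)

    def test_different_data_rejected(self, default_sens):
        b = np.array([0.8])
        conf = ConfidenceParams(0.5, 0.0, b)
        c1 = _counts_from_probs(default_sens, conf, 1000)
        c2 = _counts_from_probs(default_sens, conf, 2000)
        f0 = fit_cncb(c1, "no_boost", options={"polish": False,
                                               "nm_maxiter": 30})
        f1 = fit_cncb(c2, "with_boost", options={"polish": False,
                                                 "nm_maxiter": 30})
        with pytest.raises(ValueError):
            lr_test(f0, f1)
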