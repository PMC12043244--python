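"""Continuous ratings: distortion, evidence mapping, densities, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from cncb import (
    ConfidenceParams,
    DistortionParams,
    distort,
    evidence_to_probability,
    log_odds,
    rating_density,
    simulate_continuous_dataset,
    undistort,
)
from cncb.continuous import fit_continuous


class TestLogOdds:
    def test_half_is_zero(self):
        assert log_odds(0.5) == 0.0

    def test_antisymmetry(self):
        for p in (0.1, 0.3, 0.77, 0.99):
            assert log_odds(p) + log_odds(1 - p) == pytest.approx(0, abs=1e-12)

    def test_three_quarters(self):
        assert log_odds(0.75) == pytest.approx(np.log(3), abs=1e-14)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            log_odds(0.0)
        with pytest.raises(ValueError):
            log_odds(1.0)


class TestDistortion:
    def test_gamma_one_is_identity_for_any_p0(self):
        for p0 in (0.2, 0.5, 0.9):
            d = DistortionParams(1.0, p0)
            p = np.linspace(0.01, 0.99, 23)
            np.testing.assert_allclose(distort(p, d), p, atol=1e-12)

    def test_fixed_point(self):
        for gamma in (0.3, 1.7):
            d = DistortionParams(gamma, 0.4)
            assert distort(0.4, d) == pytest.approx(0.4, abs=1e-12)

    def test_closed_form_example(self):
        # direct evaluation of the log-odds affine map
        d = DistortionParams(0.5, 0.4)
        lo = 0.5 * np.log(0.9 / 0.1) + 0.5 * np.log(0.4 / 0.6)
        expected = 1 / (1 + np.exp(-lo))
        assert distort(0.9, d) == pytest.approx(expected, abs=1e-14)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        p=st.floats(0.01, 0.99),
        gamma=st.floats(0.5, 2.0),
        p0=st.floats(0.2, 0.8),
    )
    def test_round_trip_and_monotonicity(self, p, gamma, p0):
        # parameter box where the distorted probability stays far enough
        # from the representable ends of (0, 1) for exact inversion
        d = DistortionParams(gamma, p0)
        assert undistort(distort(p, d), d) == pytest.approx(p, abs=1e-12)
        eps = 1e-6
        if p + eps < 0.99:
            assert distort(p + eps, d) > distort(p, d)

    def test_round_trip_study_range_extremes(self):
        # the full study range of gamma, at a looser float tolerance
        for gamma in (0.25, 4.0):
            d = DistortionParams(gamma, 0.4)
            for p in (1e-3, 0.5, 1 - 1e-3):
                assert undistort(distort(p, d), d) == pytest.approx(
                    p, rel=1e-6)


class TestEvidenceToProbability:
    def test_monotone_on_symmetric_design(self, default_sens):
        conf = ConfidenceParams(0.5, 0.2, None)
        x = np.linspace(-4, 4, 301)
        g = evidence_to_probability(x, default_sens, conf)
        assert np.all(np.diff(g) > 0)

    def test_matches_monte_carlo_fraction_correct(self, default_sens):
        conf = ConfidenceParams(0.5, 0.2, None)
        rng = np.random.default_rng(0)
        n = 2_000_000
        mu = np.where(rng.random(n) < 0.5, 0.67, -0.67)
        eps = rng.standard_normal(n)
        s = mu + eps
        d = np.where(s > 0, 1, -1)
        w = mu + 0.8 * eps + 0.5 * rng.standard_normal(n)
        v = d * w
        correct = d == np.sign(mu)
        for x0 in (-1.0, 0.0, 0.8, 2.0):
            sel = np.abs(v - x0) < 0.025
            mc = correct[sel].mean()
            se = np.sqrt(mc * (1 - mc) / sel.sum())
            model = evidence_to_probability(x0, default_sens, conf)
            assert abs(model - mc) < 3 * se + 2e-3

    def test_prior_weighting_changes_map_on_asymmetric_design(self):
        # on a mirror-symmetric two-stimulus design the prior cancels out
        # of the correctness posterior; an asymmetric design breaks that
        from cncb import SensoryParams

        sens = SensoryParams(mu=np.array([-0.3, 0.9]))
        conf = ConfidenceParams(0.5, 0.2, None)
        g_unif = evidence_to_probability(1.0, sens, conf)
        g_skew = evidence_to_probability(1.0, sens, conf, prior=[0.9, 0.1])
        assert g_unif != pytest.approx(g_skew, abs=1e-6)

    def test_prior_irrelevant_on_symmetric_design(self, default_sens):
        conf = ConfidenceParams(0.5, 0.2, None)
        g_unif = evidence_to_probability(1.0, default_sens, conf)
        g_skew = evidence_to_probability(1.0, default_sens, conf,
                                         prior=[0.7, 0.3])
        assert g_unif == pytest.approx(g_skew, abs=1e-12)


class TestRatingDensity:
    @pytest.mark.parametrize("gamma,p0", [(1.0, 0.5), (0.5, 0.4)])
    def test_normalizes_per_stimulus(self, default_sens, gamma, p0):
        conf = ConfidenceParams(0.5, 0.2, None)
        dist = DistortionParams(gamma, p0)
        for i in (0, 1):
            mass = sum(
                quad(lambda r: rating_density(r, i, j, default_sens, conf,
                                              dist),
                     1e-4, 1 - 1e-4, limit=200)[0]
                for j in (-1, 1)
            )
            assert mass == pytest.approx(1.0, abs=1e-4)

    def test_unbiased_map_skews_ratings_high(self, default_sens):
        conf = ConfidenceParams(0.5, 0.2, None)
        rng = np.random.default_rng(4)
        df = simulate_continuous_dataset(default_sens, conf,
                                         DistortionParams(1.0, 0.5),
                                         50_000, rng)
        r = df["confidence_cont"]
        assert r.median() > 0.7
        assert (r > 0.8).mean() > 2 * (r < 0.2).mean()

    def test_compressive_distortion_centres_ratings(self, default_sens):
        conf = ConfidenceParams(0.5, 0.2, None)
        rng = np.random.default_rng(4)
        mid = DistortionParams(0.5, 0.4)
        d_mid = simulate_continuous_dataset(default_sens, conf, mid,
                                            50_000, rng)
        frac_mid = ((d_mid.confidence_cont > 0.35)
                    & (d_mid.confidence_cont < 0.75)).mean()
        d_unb = simulate_continuous_dataset(default_sens, conf,
                                            DistortionParams(1.0, 0.5),
                                            50_000, np.random.default_rng(4))
        frac_unb = ((d_unb.confidence_cont > 0.35)
                    & (d_unb.confidence_cont < 0.75)).mean()
        assert frac_mid > frac_unb + 0.2

    def test_histogram_matches_density(self, default_sens):
        conf = ConfidenceParams(0.5, 0.2, None)
        dist = DistortionParams(0.5, 0.4)
        rng = np.random.default_rng(8)
        df = simulate_continuous_dataset(default_sens, conf, dist,
                                         100_000, rng)
        sel = df[(df.stimulus > 0)]
        edges = np.linspace(0.02, 0.98, 25)
        hist, _ = np.histogram(sel.confidence_cont, bins=edges)
        emp = hist / len(sel)
        model = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            tot = sum(
                quad(lambda r: rating_density(r, 1, j, default_sens, conf,
                                              dist), lo, hi, limit=100)[0]
                for j in (-1, 1)
            )
            model.append(tot)
        tv = 0.5 * np.abs(np.asarray(model) - emp).sum()
        assert tv < 0.02


class TestContinuousFit:
    def test_recovers_distortion_and_confidence_parameters(self,
                                                           default_sens):
        conf = ConfidenceParams(0.5, 0.2, None)
        dist = DistortionParams(0.5, 0.4)
        rng = np.random.default_rng(11)
        df = simulate_continuous_dataset(default_sens, conf, dist,
                                         10_000, rng)
        res = fit_continuous(df)
        assert res.converged
        assert res.dist.gamma == pytest.approx(0.5, abs=0.1)
        assert res.dist.p0 == pytest.approx(0.4, abs=0.1)
        assert res.conf.sigma_c == pytest.approx(0.5, abs=0.2)
        assert res.conf.alpha == pytest.approx(0.2, abs=0.2)
        assert res.p0_identified

    def test_identity_distortion_flags_p0(self, default_sens):
        conf = ConfidenceParams(0.5, 0.2, None)
        rng = np.random.default_rng(5)
        df = simulate_continuous_dataset(default_sens, conf,
                                         DistortionParams(1.0, 0.5),
                                         10_000, rng)
        res = fit_continuous(df)
        assert res.dist.gamma == pytest.approx(1.0, abs=0.05)
        assert not res.p0_identified
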