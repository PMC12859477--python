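"""The ZINB + NB mixture: pmfs, maximum likelihood, posteriors, calling."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from guidecall import (
    GuideMixtureModel,
    MixtureParams,
    fit_mixture,
    mixture_loglik,
    nb_logpmf,
    posterior_high,
    weighted_nb_mle,
    zinb_logpmf,
)

from conftest import MIXTURE_REGIME as REGIME
from conftest import sample_mixture


def truncation_grid(mu: float, r: float) -> np.ndarray:
    upper = int(mu + 50 * np.sqrt(mu + mu**2 / r)) + 1
    return np.arange(upper)


class TestNbLogpmf:
    def test_closed_form_at_zero(self):
        mu, r = 3.7, 1.9
        assert nb_logpmf(0, mu, r) == pytest.approx(r * (np.log(r) - np.log(r + mu)))

    def test_poisson_limit(self):
        # r -> infinity: NB(mu, r) -> Poisson(mu); P(2) = e^-2 * 2^2 / 2!
        assert np.exp(nb_logpmf(2, 2.0, 1e6)) == pytest.approx(
            np.exp(-2) * 2, abs=1e-3
        )

    @pytest.mark.parametrize("mu", [0.1, 1.0, 10.0, 100.0])
    @pytest.mark.parametrize("r", [0.2, 1.0, 5.0, 50.0])
    def test_normalizes_and_matches_scipy(self, mu, r):
        x = truncation_grid(mu, r)
        lp = nb_logpmf(x, mu, r)
        assert np.exp(lp).sum() == pytest.approx(1.0, abs=1e-6)
        ref = scipy.stats.nbinom.logpmf(x, r, r / (r + mu))
        np.testing.assert_allclose(lp, ref, rtol=1e-10, atol=1e-12)

    @pytest.mark.parametrize("bad_x", [-1, 0.5, np.nan])
    def test_invalid_x_rejected(self, bad_x):
        with pytest.raises(ValueError):
            nb_logpmf(bad_x, 1.0, 1.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            nb_logpmf(1, 0.0, 1.0)
        with pytest.raises(ValueError):
            nb_logpmf(1, 1.0, -1.0)


class TestZinbLogpmf:
    def test_reduces_to_nb_when_no_inflation(self):
        x = np.arange(30)
        np.testing.assert_allclose(zinb_logpmf(x, 0.0, 2.5, 1.3), nb_logpmf(x, 2.5, 1.3))

    def test_zero_mass_dominated_by_inflation_at_large_mean(self):
        assert zinb_logpmf(0, 0.5, 1e6, 1.0) == pytest.approx(np.log(0.5), abs=1e-4)

    @pytest.mark.parametrize("w0", [0.0, 0.5])
    @pytest.mark.parametrize("mu,r", [(0.1, 0.2), (1.0, 1.0), (10.0, 5.0), (100.0, 50.0)])
    def test_normalizes(self, w0, mu, r):
        x = truncation_grid(mu, r)
        assert np.exp(zinb_logpmf(x, w0, mu, r)).sum() == pytest.approx(1.0, abs=1e-6)

    def test_matches_direct_mixture_formula(self):
        x = np.arange(20)
        w0, mu, r = 0.37, 2.2, 0.8
        direct = np.log(
            w0 * (x == 0) + (1 - w0) * scipy.stats.nbinom.pmf(x, r, r / (r + mu))
        )
        np.testing.assert_allclose(zinb_logpmf(x, w0, mu, r), direct, rtol=1e-10)


class TestMixtureLoglik:
    def test_degenerate_mixture_is_single_nb(self):
        th = MixtureParams(pi=1 - 1e-13, w0=0.0, mu_lo=0.5, r_lo=1.0, mu_hi=40.0, r_hi=2.0)
        assert mixture_loglik([17], th) == pytest.approx(float(nb_logpmf(17, 40.0, 2.0)), abs=1e-9)

    def test_additive_over_identical_cells(self):
        th = MixtureParams(**REGIME)
        one = mixture_loglik([3], th)
        assert mixture_loglik([3, 3], th) == pytest.approx(2 * one, rel=1e-12)

    def test_matches_per_cell_summation_oracle(self):
        rng = np.random.default_rng(1)
        th = MixtureParams(pi=0.23, w0=0.4, mu_lo=0.9, r_lo=0.7, mu_hi=55.0, r_hi=3.0)
        counts = rng.integers(0, 200, size=20)
        naive = sum(
            np.log(
                (1 - th.pi)
                * (
                    th.w0 * (x == 0)
                    + (1 - th.w0) * scipy.stats.nbinom.pmf(x, th.r_lo, th.r_lo / (th.r_lo + th.mu_lo))
                )
                + th.pi * scipy.stats.nbinom.pmf(x, th.r_hi, th.r_hi / (th.r_hi + th.mu_hi))
            )
            for x in counts
        )
        assert mixture_loglik(counts, th) == pytest.approx(naive, abs=1e-10)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mixture_loglik([], MixtureParams(**REGIME))


class TestMixtureParams:
    def test_mean_ordering_enforced(self):
        with pytest.raises(ValueError, match="mu_hi > mu_lo"):
            MixtureParams(pi=0.1, w0=0.1, mu_lo=5.0, r_lo=1.0, mu_hi=4.0, r_hi=1.0)

    @pytest.mark.parametrize("field,value", [("pi", 0.0), ("pi", 1.0), ("w0", 1.0), ("r_hi", 0.0)])
    def test_out_of_range_rejected(self, field, value):
        kw = dict(REGIME)
        kw[field] = value
        with pytest.raises(ValueError):
            MixtureParams(**kw)


class TestWeightedNbMle:
    def test_recovers_parameters_from_large_sample(self):
        rng = np.random.default_rng(42)
        mu, r = 10.0, 2.0
        x = rng.negative_binomial(r, r / (r + mu), size=50_000)
        mu_hat, r_hat = weighted_nb_mle(x, np.ones_like(x, dtype=float))
        assert mu_hat == pytest.approx(mu, rel=0.02)
        assert r_hat == pytest.approx(r, rel=0.10)

    def test_moment_estimate_agrees_with_mle(self):
        rng = np.random.default_rng(42)
        mu, r = 10.0, 2.0
        x = rng.negative_binomial(r, r / (r + mu), size=50_000)
        m, s2 = x.mean(), x.var()
        r_mom = m**2 / (s2 - m)
        _, r_hat = weighted_nb_mle(x, np.ones_like(x, dtype=float))
        assert abs(r_mom - r_hat) / r_hat < 0.25

    def test_constant_counts_hit_dispersion_cap(self):
        x = np.full(50, 7)
        mu_hat, r_hat = weighted_nb_mle(x, np.ones_like(x, dtype=float))
        assert mu_hat == pytest.approx(7.0)
        assert r_hat == pytest.approx(np.exp(10))

    def test_weighting_changes_the_estimate(self):
        x = np.array([0, 0, 10, 10])
        w_lo = np.array([1.0, 1.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            weighted_nb_mle(x, w_lo)  # weighted mean zero
        mu_hat, _ = weighted_nb_mle(x, 1 - w_lo)
        assert mu_hat == pytest.approx(10.0)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="effective sample"):
            weighted_nb_mle(np.array([1, 2]), np.zeros(2))


class TestFitMixture:
    def test_parameter_recovery_at_screen_regime(self):
        x = sample_mixture(20_000, seed=7)
        res = fit_mixture(x, seed=0)
        assert res.status == "ok"
        assert abs(res.params.mu_hi - 100.0) / 100.0 < 0.10
        assert abs(res.params.pi - 0.1) < 0.02

    def test_fitted_likelihood_dominates_truth(self):
        x = sample_mixture(20_000, seed=7)
        res = fit_mixture(x, seed=0)
        assert res.loglik >= mixture_loglik(x, MixtureParams(**REGIME))

    def test_em_trace_monotone(self):
        x = sample_mixture(5_000, seed=3)
        res = fit_mixture(x, seed=0)
        diffs = np.diff(res.loglik_trace)
        assert np.all(diffs >= -1e-8)

    def test_constraint_holds_on_output(self):
        for seed in range(3):
            x = sample_mixture(2_000, seed=seed)
            res = fit_mixture(x, seed=0)
            if res.params is not None:
                assert res.params.mu_hi > res.params.mu_lo

    def test_all_zeros_degenerate_fallback(self):
        res = fit_mixture(np.zeros(100, dtype=int))
        assert res.status == "degenerate_fallback"
        assert res.params is None
        assert res.n_positive == 0

    def test_min_positive_gate(self):
        x = np.zeros(100, dtype=int)
        x[:4] = [5, 8, 3, 9]
        gated = fit_mixture(x, min_positive=5)
        assert gated.status == "degenerate_fallback"
        assert gated.n_iter == 0  # never entered EM
        ungated = fit_mixture(x, min_positive=4)
        assert ungated.n_iter > 0  # EM ran; status then depends on evidence

    def test_background_only_counts_not_forced_into_mixture(self):
        # pure ambient ZINB draws: no expressing component is supported
        rng = np.random.default_rng(11)
        nonzero = rng.random(2000) >= 0.7
        x = np.where(nonzero, rng.negative_binomial(1.0, 1 / 1.5, 2000), 0)
        res = fit_mixture(x, seed=0)
        assert res.status == "degenerate_fallback" or res.params.pi < 0.05

    def test_clear_two_population_counts_stay_ok(self):
        x = sample_mixture(5_000, seed=12)
        assert fit_mixture(x, seed=0).status == "ok"

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            GuideMixtureModel([1])


class TestPosterior:
    def test_pi_near_one_forces_high_posterior(self):
        th = MixtureParams(pi=1 - 1e-12, w0=0.5, mu_lo=0.5, r_lo=1.0, mu_hi=50.0, r_hi=2.0)
        p = posterior_high(th, np.arange(100))
        assert np.all(p > 0.999)

    def test_large_counts_more_likely_expressing(self):
        th = MixtureParams(pi=0.5, w0=0.0, mu_lo=1.0, r_lo=1.0, mu_hi=100.0, r_hi=1.0)
        assert posterior_high(th, 0) < posterior_high(th, 200)

    def test_matches_pmf_ratio_oracle(self):
        rng = np.random.default_rng(0)
        x = np.arange(301)
        for _ in range(20):
            mu_lo = rng.uniform(0.1, 5)
            th = MixtureParams(
                pi=rng.uniform(0.01, 0.99),
                w0=rng.uniform(0, 0.95),
                mu_lo=mu_lo,
                r_lo=rng.uniform(0.2, 10),
                mu_hi=mu_lo + rng.uniform(1, 200),
                r_hi=rng.uniform(0.2, 10),
            )
            nb_hi = scipy.stats.nbinom.pmf(x, th.r_hi, th.r_hi / (th.r_hi + th.mu_hi))
            nb_lo = scipy.stats.nbinom.pmf(x, th.r_lo, th.r_lo / (th.r_lo + th.mu_lo))
            zinb = th.w0 * (x == 0) + (1 - th.w0) * nb_lo
            naive = th.pi * nb_hi / (th.pi * nb_hi + (1 - th.pi) * zinb)
            np.testing.assert_allclose(posterior_high(th, x), naive, atol=1e-10)

    @settings(max_examples=50, deadline=None)
    @given(
        pi=st.floats(0.01, 0.99),
        w0=st.floats(0.0, 0.9),
        mu_lo=st.floats(0.05, 10),
        gap=st.floats(0.5, 500),
        r_lo=st.floats(0.2, 20),
        r_hi=st.floats(0.2, 20),
        x=st.integers(0, 10**6),
    )
    def test_bounded_in_unit_interval(self, pi, w0, mu_lo, gap, r_lo, r_hi, x):
        th = MixtureParams(pi=pi, w0=w0, mu_lo=mu_lo, r_lo=r_lo, mu_hi=mu_lo + gap, r_hi=r_hi)
        p = float(posterior_high(th, x))
        assert 0.0 <= p <= 1.0

    def test_equal_dispersion_monotone_in_x(self):
        th = MixtureParams(pi=0.1, w0=0.0, mu_lo=0.5, r_lo=5.0, mu_hi=100.0, r_hi=5.0)
        p = posterior_high(th, np.arange(10_001))
        assert np.all(np.diff(p) >= -1e-12)


class TestClassify:
    def _results(self, counts, **kw):
        return fit_mixture(counts, **kw)

    def test_threshold_is_strictly_greater_than_half(self, monkeypatch):
        from guidecall.mixture import GuideMixtureResults

        x = sample_mixture(2_000, seed=9)
        res = self._results(x)
        monkeypatch.setattr(
            GuideMixtureResults,
            "posterior",
            lambda self, _: np.array([0.5, np.nextafter(0.5, 1.0), 0.49999]),
        )
        calls = res.classify(["b1", "b2", "b3"], "g", counts=[1, 2, 3])
        assert [c.expressed for c in calls] == [False, True, False]

    def test_zero_count_in_ambient_regime_not_expressed(self):
        x = sample_mixture(5_000, seed=2)
        res = self._results(x)
        p0 = float(res.posterior(0))
        assert p0 < 0.5
        call = res.classify(["b"], "g", counts=[0])[0]
        assert not call.expressed

    def test_threshold_count_partitions_calls(self):
        # equal dispersions: the posterior crosses 0.5 exactly once, so calls
        # are a step function of the count
        th = MixtureParams(pi=0.05, w0=0.3, mu_lo=0.5, r_lo=4.0, mu_hi=80.0, r_hi=4.0)
        x = np.arange(10_001)
        expressed = posterior_high(th, x) > 0.5
        flips = np.flatnonzero(np.diff(expressed.astype(int)))
        assert len(flips) == 1
        x_star = flips[0] + 1
        assert not expressed[x_star - 1] and expressed[x_star]

    def test_fallback_calls_use_count_threshold(self):
        x = np.zeros(50, dtype=int)
        x[0] = 4
        res = fit_mixture(x)
        assert res.status == "degenerate_fallback"
        calls = res.classify([f"b{i}" for i in range(50)], "g")
        assert calls[0].expressed  # 4 >= default fallback_min_count 3
        assert calls[0].posterior is None
        assert not any(c.expressed for c in calls[1:])

    def test_summary_mentions_fit_quality(self):
        res = fit_mixture(sample_mixture(2_000, seed=4))
        text = res.summary()
        assert "pi" in text and "log-likelihood" in text
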