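"""Mixing model: prior construction, moments, sampler vs independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import grid_posterior_mean
from isoroot.mixing_model import (
    MCMCSettings,
    PriorSpec,
    SourceDay,
    build_prior,
    concentration_adjust,
    fit_day,
    fit_season,
    gelman_rubin,
    mixture_moments,
)
from isoroot.synthetic_data import default_root_profile

DAY = pd.Timestamp("2018-07-01")


def _two_source(mu=(-4.0, -12.0), sigma=(0.3, 0.3), conc=(0.2, 0.2)):
    return SourceDay(DAY, np.array(mu), np.array(sigma), np.array(conc))


def _flat_prior(k=2):
    return PriorSpec(np.ones(k), np.full(k, 1.0 / k), np.linspace(0, 50, k + 1))


class TestPrior:
    def test_uniform_profile_equal_layers_is_flat(self):
        prior = build_prior(np.full(10, 0.1), (0, 12.5, 25, 37.5, 50))
        assert np.allclose(prior.alpha, 1.0)

    def test_default_profile_layer_integration(self):
        prior = build_prior(default_root_profile(), (0, 10, 22.5, 37.5, 50))
        assert np.allclose(prior.root_fractions, [0.41, 0.31, 0.185, 0.095], atol=1e-12)
        assert np.allclose(prior.alpha, [1.64, 1.24, 0.74, 0.38], atol=1e-12)

    def test_total_concentration_equals_layer_count(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            raw = np.sort(rng.uniform(0.02, 1.0, 10))[::-1]
            profile = raw / raw.sum()
            prior = build_prior(profile, (0, 10, 22.5, 37.5, 50))
            assert prior.alpha.sum() == pytest.approx(4.0)

    def test_zero_mass_layer_rejected(self):
        profile = np.array([0.5, 0.5] + [0.0] * 8)
        with pytest.raises(ValueError, match="zero root mass"):
            build_prior(profile, (0, 10, 22.5, 37.5, 50))


class TestConcentrationAdjust:
    def test_equal_concentrations_neutral(self):
        p = np.array([0.3, 0.5, 0.2])
        assert np.allclose(concentration_adjust(p, np.full(3, 0.2)), p)

    def test_worked_example(self):
        out = concentration_adjust(np.array([0.5, 0.5]), np.array([0.3, 0.1]))
        assert np.allclose(out, [0.75, 0.25])

    @given(st.lists(st.floats(0.01, 1), min_size=2, max_size=5))
    @settings(derandomize=True, deadline=None, max_examples=60)
    def test_stays_on_simplex(self, raw):
        p = np.array(raw) / np.sum(raw)
        c = np.linspace(0.05, 0.4, len(raw))
        out = concentration_adjust(p, c)
        assert out.sum() == pytest.approx(1.0)
        assert (out >= 0).all()


class TestMixtureMoments:
    def test_mean_is_adjusted_weighted_average(self):
        src = _two_source(mu=(-4.0, -12.0), conc=(0.3, 0.1))
        mu_mix, _ = mixture_moments(np.array([0.5, 0.5]), src)
        assert mu_mix == pytest.approx(-6.0)

    def test_variance_worked_example(self):
        src = _two_source(sigma=(0.4, 0.8))
        _, var = mixture_moments(np.array([0.75, 0.25]), src, xi=1.0)
        assert var == pytest.approx(0.13)

    def test_xi_scales_variance(self):
        src = _two_source(sigma=(0.4, 0.8))
        _, v1 = mixture_moments(np.array([0.6, 0.4]), src, xi=1.0)
        _, v3 = mixture_moments(np.array([0.6, 0.4]), src, xi=3.0)
        assert v3 == pytest.approx(3 * v1)


class TestGelmanRubin:
    def test_identical_chains_floor_at_one(self):
        chain = np.sin(np.arange(200.0))
        assert gelman_rubin(np.stack([chain, chain, chain])) == pytest.approx(1.0)

    def test_same_distribution_chains_converge(self):
        rng = np.random.default_rng(3)
        chains = rng.normal(0, 1, (3, 5000))
        assert gelman_rubin(chains) < 1.05

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(4)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert gelman_rubin(chains) > 1.5

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="two chains"):
            gelman_rubin(np.ones((1, 100)))


class TestFitDay:
    def test_balanced_observation_recovers_half(self, fast_mcmc):
        post = fit_day([-8.0, -8.0, -8.0], _two_source(), _flat_prior(), fast_mcmc)
        # closed form: p1 = (δx − δ2)/(δ1 − δ2) = 0.5
        assert post.mean[0] == pytest.approx(0.5, abs=0.05)

    def test_extreme_observation_piles_mass_at_zero(self, fast_mcmc):
        post = fit_day([-12.0, -12.0, -12.0], _two_source(), _flat_prior(), fast_mcmc)
        assert post.mean[0] < 0.15

    def test_matches_grid_oracle_two_sources(self, fast_mcmc):
        src = _two_source(conc=(0.25, 0.12))
        prior = _flat_prior()
        for obs in ([-6.5, -7.0], [-10.5, -10.0, -10.8]):
            post = fit_day(obs, src, prior, fast_mcmc)
            expect = grid_posterior_mean(
                np.array(obs), src.mu, src.sigma, src.concentration, prior.alpha
            )
            assert np.abs(post.mean - expect).max() < 0.02

    def test_matches_grid_oracle_three_sources(self):
        src = SourceDay(
            DAY, np.array([-3.0, -8.0, -11.0]), np.array([0.4, 0.3, 0.5]), np.array([0.08, 0.2, 0.3])
        )
        prior = PriorSpec(np.array([1.5, 0.9, 0.6]), np.array([0.5, 0.3, 0.2]), np.array([0, 15, 30, 50]))
        obs = [-7.5, -8.2, -7.9]
        # three free parameters need longer chains than the two-source cases
        # for Monte-Carlo error comfortably below the 0.02 oracle tolerance
        post = fit_day(
            obs, src, prior, MCMCSettings(chain_length=10_000, burn_in=5_000, thin=5, seed=42)
        )
        expect = grid_posterior_mean(np.array(obs), src.mu, src.sigma, src.concentration, prior.alpha)
        assert np.abs(post.mean - expect).max() < 0.02

    def test_draws_and_means_on_simplex(self, fast_mcmc):
        post = fit_day([-8.0], _two_source(), _flat_prior(), fast_mcmc)
        assert np.allclose(post.draws.sum(axis=1), 1.0, atol=1e-9)
        assert post.mean.sum() == pytest.approx(1.0, abs=1e-9)
        assert (post.draws >= 0).all()

    def test_uninformative_likelihood_returns_prior_mean(self, fast_mcmc):
        """Identical sources leave the data silent; posterior ≈ Dirichlet prior."""
        src = SourceDay(DAY, np.array([-8.0, -8.0, -8.0]), np.full(3, 0.3), np.full(3, 0.2))
        alpha = np.array([1.8, 0.8, 0.4])
        prior = PriorSpec(alpha, alpha / 3, np.array([0, 15, 30, 50]))
        post = fit_day([-8.0], src, prior, fast_mcmc)
        assert np.abs(post.mean - alpha / alpha.sum()).max() < 0.05

    def test_same_seed_identical_draws(self, fast_mcmc):
        a = fit_day([-8.0, -7.5], _two_source(), _flat_prior(), fast_mcmc)
        b = fit_day([-8.0, -7.5], _two_source(), _flat_prior(), fast_mcmc)
        assert np.array_equal(a.draws, b.draws)
        assert np.array_equal(a.xi_draws, b.xi_draws)

    def test_degenerate_all_zero_sigma_rejected(self, fast_mcmc):
        src = _two_source(sigma=(0.0, 0.0))
        with pytest.raises(ValueError, match="SDs are zero"):
            fit_day([-8.0], src, _flat_prior(), fast_mcmc)

    def test_nonfinite_observation_rejected(self, fast_mcmc):
        with pytest.raises(ValueError, match="non-finite"):
            fit_day([np.nan], _two_source(), _flat_prior(), fast_mcmc)

    def test_retained_draw_count(self):
        settings_ = MCMCSettings(chain_length=4000, burn_in=2000, thin=2, n_chains=3, seed=0)
        post = fit_day([-8.0], _two_source(), _flat_prior(), settings_)
        assert post.draws.shape == (3 * 1000, 2)


class TestFitSeason:
    def _sources(self, dates):
        return {
            d: SourceDay(d, np.array([-4.0, -12.0]), np.array([0.3, 0.3]), np.array([0.2, 0.2]))
            for d in dates
        }

    def test_constant_truth_recovered_across_days(self, fast_mcmc):
        dates = pd.date_range("2018-07-01", periods=3, freq="D")
        xylem = {d: [-8.0, -8.1, -7.9] for d in dates}
        posts, skipped = fit_season(xylem, self._sources(dates), _flat_prior(), fast_mcmc)
        assert not skipped
        for post in posts.values():
            lo, hi = post.quantiles((0.025, 0.975))[:, 0]
            assert lo < 0.5 < hi

    def test_day_without_xylem_reported_skipped(self, fast_mcmc):
        dates = pd.date_range("2018-07-01", periods=3, freq="D")
        xylem = {dates[0]: [-8.0], dates[2]: [-8.0]}
        posts, skipped = fit_season(xylem, self._sources(dates), _flat_prior(), fast_mcmc)
        assert dates[1] in skipped
        assert set(posts) == {dates[0], dates[2]}

    def test_season_deterministic_under_seed(self, fast_mcmc):
        dates = pd.date_range("2018-07-01", periods=2, freq="D")
        xylem = {d: [-8.0] for d in dates}
        a, _ = fit_season(xylem, self._sources(dates), _flat_prior(), fast_mcmc)
        b, _ = fit_season(xylem, self._sources(dates), _flat_prior(), fast_mcmc)
        for d in dates:
            assert np.array_equal(a[d].draws, b[d].draws)
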