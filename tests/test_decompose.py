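import numpy as np
import pandas as pd
import pytest

from phenodecomp.decompose import (PriorSpec, SlopePosterior, VarianceComponentDraws,
                                   aggregate_populations, decide_interval,
                                   fit_bivariate_mixed, gibbs_variance_components,
                                   slopes_from_vcv, test_local_adaptation)
from phenodecomp.mcmc import PosteriorSummary, effective_sample_size


class TestAggregation:
    def _sites(self, coords):
        return pd.DataFrame({"site_id": [f"s{i}" for i in range(len(coords))],
                             "easting_m": [c[0] for c in coords],
                             "northing_m": [c[1] for c in coords]})

    def test_same_population(self):
        pops = aggregate_populations(self._sites([(10_000, 20_000), (40_000, 49_000)]), 50_000)
        assert pops["s0"] == pops["s1"] == "0:0"

    def test_floor_division(self):
        pops = aggregate_populations(self._sites([(60_000, 10_000)]), 50_000)
        assert pops["s0"] == "1:0"

    def test_zero_grid_is_site_level(self):
        pops = aggregate_populations(self._sites([(1, 2), (3, 4), (5, 6)]), 0)
        assert pops.nunique() == 3

    def test_negative_grid_rejected(self):
        with pytest.raises(ValueError):
            aggregate_populations(self._sites([(0, 0)]), -5)


def _draws_from_sigmas(sigma_pop, sigma_year, n=200):
    sp = np.repeat(np.asarray(sigma_pop, dtype=float)[None], n, axis=0)
    sy = np.repeat(np.asarray(sigma_year, dtype=float)[None], n, axis=0)
    return VarianceComponentDraws(
        mu=np.zeros((n, 2)),
        sigma={"population": sp, "year": sy, "residual": np.repeat(np.eye(2)[None], n, axis=0)},
        terms=("population", "year"), n_obs=0, n_levels={}, seed=0)


class TestSlopeFunctionals:
    def test_hand_arithmetic(self):
        draws = _draws_from_sigmas([[1.0, -3.0], [-3.0, 10.0]], [[2.0, -4.0], [-4.0, 40.0]])
        post = slopes_from_vcv(draws)
        assert np.allclose(post.b_time, -2.0)       # -4 / 2
        assert np.allclose(post.b_space, -3.0)      # -3 / 1
        assert np.allclose(post.delta_b, -1.0)

    def test_diagonal_gives_zero_slope(self):
        draws = _draws_from_sigmas(np.diag([2.0, 5.0]), np.diag([1.0, 7.0]))
        post = slopes_from_vcv(draws)
        assert np.allclose(post.b_time, 0.0) and np.allclose(post.b_space, 0.0)

    def test_delta_identity_drawwise(self):
        rng = np.random.default_rng(0)
        n = 300
        sp = np.empty((n, 2, 2))
        sy = np.empty((n, 2, 2))
        for i in range(n):
            a = rng.normal(size=(2, 2))
            sp[i] = a @ a.T + 0.1 * np.eye(2)
            b = rng.normal(size=(2, 2))
            sy[i] = b @ b.T + 0.1 * np.eye(2)
        draws = VarianceComponentDraws(np.zeros((n, 2)),
                                       {"population": sp, "year": sy, "residual": sp},
                                       ("population", "year"), 0, {}, 0)
        post = slopes_from_vcv(draws)
        assert np.array_equal(post.delta_b, post.b_space - post.b_time)


class TestDecisionRule:
    @pytest.mark.parametrize("lo,hi,expect", [
        (0.35, 4.21, True),      # interval above zero
        (-2.63, 2.71, False),    # spans zero
        (0.0, 1.0, False),       # boundary counts as spanning
        (-4.0, -0.5, True),
    ])
    def test_interval_decision(self, lo, hi, expect):
        assert decide_interval(lo, hi) is expect

    def test_direction_labels(self):
        def posterior(center, width):
            draws = np.random.default_rng(0).normal(center, width / 4, 1000)
            s = {"delta_b": PosteriorSummary(center, center - width / 2, center + width / 2,
                                             center, width / 4)}
            return SlopePosterior(draws, draws, draws, s)

        t = test_local_adaptation(posterior(2.38, 3.86))
        assert t.reject and t.direction == "countergradient"
        t = test_local_adaptation(posterior(-5.9, 4.0))
        assert t.reject and t.direction == "co-gradient"
        t = test_local_adaptation(posterior(0.0, 5.0))
        assert not t.reject and t.direction is None


def _model_simulated_obs(seed, n_pop=60, n_year=20,
                         s_pop=((1.5, -6.0), (-6.0, 36.0)),
                         s_year=((1.0, -6.4), (-6.4, 50.0)),
                         s_res=((0.05, 0.0), (0.0, 25.0))):
    """Data drawn directly from the bivariate variance-components model."""
    rng = np.random.default_rng(seed)
    u = rng.multivariate_normal([0, 0], s_pop, n_pop)
    v = rng.multivariate_normal([0, 0], s_year, n_year)
    e = rng.multivariate_normal([0, 0], s_res, n_pop * n_year)
    pop = np.repeat(np.arange(n_pop), n_year)
    year = np.tile(np.arange(n_year), n_pop)
    Z = np.array([9.0, 60.0]) + u[pop] + v[year] + e
    return pd.DataFrame({"population_id": pop, "year": year, "site_id": pop,
                         "temp": Z[:, 0], "phen": Z[:, 1]})


class TestGibbsSampler:
    def test_recovers_known_covariances(self):
        """Posterior means of all six distinct covariance entries lie within
        3 posterior SDs of the generating values."""
        obs = _model_simulated_obs(seed=10, n_pop=100, n_year=25)
        fit = fit_bivariate_mixed(obs, n_iter=4000, burn_in=1000, thin=3, seed=0)
        truth = {"population": np.array([[1.5, -6.0], [-6.0, 36.0]]),
                 "year": np.array([[1.0, -6.4], [-6.4, 50.0]]),
                 "residual": np.array([[0.05, 0.0], [0.0, 25.0]])}
        for term, S in truth.items():
            d = fit.draws.sigma[term]
            for i, j in [(0, 0), (0, 1), (1, 1)]:
                mean, sd = d[:, i, j].mean(), d[:, i, j].std(ddof=1)
                assert abs(mean - S[i, j]) < 3 * sd, (term, i, j, mean, S[i, j])

    def test_exact_linear_limit(self):
        """phen exactly linear in temp with population structure only: the
        among-population slope concentrates at the generating value."""
        pops = np.repeat(np.arange(30), 10)
        temp = pops * 0.3 + 5.0
        obs = pd.DataFrame({"population_id": pops, "year": np.tile(np.arange(10), 30),
                            "site_id": pops, "temp": temp, "phen": 100.0 - 5.0 * temp})
        fit = fit_bivariate_mixed(obs, n_iter=4000, burn_in=1000, thin=3, seed=0,
                                  terms=("population",))
        post = slopes_from_vcv(fit, year_term="population")
        assert abs(post.summary["b_space"].mode + 5.0) < 0.05

    def test_scale_equivariance_of_slopes(self):
        """Multiplying temperatures by k divides the slope posteriors by k."""
        obs = _model_simulated_obs(seed=3, n_pop=60, n_year=20)
        fit1 = fit_bivariate_mixed(obs, n_iter=3000, burn_in=1000, thin=2, seed=1)
        obs2 = obs.assign(temp=obs["temp"] * 2.0)
        fit2 = fit_bivariate_mixed(obs2, n_iter=3000, burn_in=1000, thin=2, seed=1)
        p1, p2 = slopes_from_vcv(fit1), slopes_from_vcv(fit2)
        for k in ("b_time", "b_space"):
            m1, m2 = p1.summary[k].mode, p2.summary[k].mode
            assert m2 == pytest.approx(m1 / 2.0, abs=0.15 * abs(m1))

    def test_location_shift_leaves_slopes(self):
        obs = _model_simulated_obs(seed=4, n_pop=50, n_year=15)
        fit1 = fit_bivariate_mixed(obs, n_iter=3000, burn_in=1000, thin=2, seed=2)
        obs2 = obs.assign(temp=obs["temp"] + 7.0, phen=obs["phen"] - 13.0)
        fit2 = fit_bivariate_mixed(obs2, n_iter=3000, burn_in=1000, thin=2, seed=2)
        p1, p2 = slopes_from_vcv(fit1), slopes_from_vcv(fit2)
        assert p2.summary["b_time"].mode == pytest.approx(p1.summary["b_time"].mode, abs=0.3)

    def test_degenerate_inputs_rejected(self):
        obs = _model_simulated_obs(seed=5, n_pop=10, n_year=5)
        with pytest.raises(ValueError, match="identical|constant"):
            fit_bivariate_mixed(obs.assign(temp=4.2), n_iter=100, burn_in=10)
        with pytest.raises(ValueError, match="levels"):
            gibbs_variance_components(np.random.default_rng(0).normal(size=(20, 1)),
                                      {"g": np.zeros(20)}, n_iter=100, burn_in=10)

    def test_retained_draw_count_and_determinism(self):
        obs = _model_simulated_obs(seed=6, n_pop=20, n_year=8)
        fit1 = fit_bivariate_mixed(obs, n_iter=1300, burn_in=300, thin=10, seed=7)
        fit2 = fit_bivariate_mixed(obs, n_iter=1300, burn_in=300, thin=10, seed=7)
        assert fit1.draws.n_draws == 100
        assert np.array_equal(fit1.draws.sigma["year"], fit2.draws.sigma["year"])

    def test_prior_spec_validation(self):
        with pytest.raises(ValueError):
            PriorSpec(nu=-1.0).scale_matrix(2)
        with pytest.raises(ValueError):
            PriorSpec(V=np.array([[1.0, 2.0], [2.0, 1.0]])).scale_matrix(2)  # not PD
        assert np.allclose(PriorSpec().scale_matrix(2), 0.002 * np.eye(2))
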