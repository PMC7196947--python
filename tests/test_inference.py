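"""MAP grid estimation: priors, posterior grids, marginal-mean estimates."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from revlearn import (PriorSpec, Session, TaskConfig, estimate_parameters,
                      evaluate_log_prior, evaluate_posterior_grid, fit_session,
                      simulate_session)
from revlearn.exceptions import ConfigError, DataError
from revlearn.inference import GridAxis, PosteriorGrid
from revlearn.models import Params

from .test_models import oracle_loglik


def empty_session() -> Session:
    return Session(choices=np.array([], dtype=int), high_sides=np.array([], dtype=int),
                   outcomes=np.array([], dtype=int))


class TestPriors:
    def test_beta_prior_closed_form(self, priors):
        # Beta(1.5, 1.5) density at 1/2 is 4/pi
        assert priors.log_prior("alpha_pos", 0.5) == pytest.approx(math.log(4 / math.pi),
                                                                   abs=1e-12)

    def test_normal_prior_at_mean(self, priors):
        assert priors.log_prior("pi", 0.5) == pytest.approx(
            -math.log(0.5 * math.sqrt(2 * math.pi)), abs=1e-12)

    def test_learning_rate_density_vanishes_at_endpoints(self, priors):
        assert priors.log_prior("alpha_neg", 0.0) == -np.inf
        assert priors.log_prior("alpha_neg", 1.0) == -np.inf

    def test_beta_renormalized_over_truncated_support(self, priors):
        ax = priors.axis("beta")
        mass = stats.norm.cdf(ax.hi, 2, 2) - stats.norm.cdf(ax.lo, 2, 2)
        grid = np.linspace(ax.lo, ax.hi, 20001)
        integral = np.trapezoid(np.exp(priors.log_prior("beta", grid)), grid)
        assert integral == pytest.approx(1.0, abs=1e-4)
        assert priors.log_prior("beta", -1.0) == -np.inf
        assert priors.log_prior("beta", 2.0) == pytest.approx(
            stats.norm.logpdf(2.0, 2, 2) - math.log(mass), abs=1e-12)

    def test_evaluate_log_prior_sums_over_free_params(self, priors):
        p = Params(alpha_pos=0.5, alpha_neg=0.3, pi=0.5, beta=2.0)
        total = evaluate_log_prior(p, "RW3", priors)
        parts = (priors.log_prior("alpha_pos", 0.5) + priors.log_prior("alpha_neg", 0.3)
                 + priors.log_prior("pi", 0.5) + priors.log_prior("beta", 2.0))
        assert total == pytest.approx(float(parts), abs=1e-12)

    def test_degenerate_axis_rejected(self):
        with pytest.raises(ConfigError):
            GridAxis(0.0, 1.0, 1)


class TestPosteriorGrid:
    def test_masses_sum_to_one(self, rw3_session, coarse_priors):
        grid = evaluate_posterior_grid(rw3_session, "RW3", coarse_priors)
        assert grid.masses().sum() == pytest.approx(1.0, abs=1e-8)

    def test_empty_session_recovers_prior_mean(self, priors):
        grid = evaluate_posterior_grid(empty_session(), "RW1", priors)
        est = estimate_parameters(grid)
        assert est["alpha"] == pytest.approx(0.5, abs=0.01)  # Beta(1.5,1.5) mean
        # beta: mean of Normal(2,2) truncated to [0,10]; the rectangle-rule
        # grid overweights the truncation boundary, hence the looser band
        a, b = (0 - 2) / 2, (10 - 2) / 2
        want = stats.truncnorm.mean(a, b, loc=2, scale=2)
        assert est["beta"] == pytest.approx(want, abs=0.1)

    def test_matches_exhaustive_enumeration(self, priors):
        """Two-point grids, two-trial session: enumerate all 16 RW3 nodes by
        hand (independent sequential likelihood + scipy prior densities)."""
        two = lambda lo, hi: GridAxis(lo, hi, 2)
        small = PriorSpec(grids={"alpha_pos": two(0.2, 0.8), "alpha_neg": two(0.3, 0.7),
                                 "pi": two(-0.5, 1.0), "beta": two(1.0, 4.0),
                                 "alpha": two(0.2, 0.8), "eta": two(0.2, 0.8)})
        session = Session(choices=[0, 1], high_sides=[0, 0], outcomes=[1, 0])
        grid = evaluate_posterior_grid(session, "RW3", small)
        b_mass = stats.norm.cdf(4.0, 2, 2) - stats.norm.cdf(1.0, 2, 2)
        axes = [small.axis(n).values for n in ("alpha_pos", "alpha_neg", "pi", "beta")]
        for idx in itertools.product(range(2), repeat=4):
            ap, an, pi, beta = (axes[i][j] for i, j in enumerate(idx))
            ll = oracle_loglik(session.choices, session.outcomes, "RW3",
                               {"alpha_pos": ap, "alpha_neg": an, "pi": pi, "beta": beta})
            lp = (stats.beta.logpdf(ap, 1.5, 1.5) + stats.beta.logpdf(an, 1.5, 1.5)
                  + stats.norm.logpdf(pi, 0.5, 0.5)
                  + stats.norm.logpdf(beta, 2, 2) - math.log(b_mass))
            assert grid.log_posterior[idx] == pytest.approx(ll + lp, abs=1e-10)

    def test_point_mass_estimate_is_node(self):
        axes = (np.array([0.1, 0.5, 0.9]), np.array([1.0, 2.0]))
        lp = np.full((3, 2), -1e6)
        lp[2, 0] = 0.0  # all mass on (0.9, 1.0)
        from scipy.special import logsumexp
        grid = PosteriorGrid(model="RW1", param_names=("alpha", "beta"), axes=axes,
                             log_posterior=lp, log_loglik=lp, log_cell=0.0,
                             log_norm=float(logsumexp(lp)))
        est = estimate_parameters(grid)
        assert est["alpha"] == pytest.approx(0.9)
        assert est["beta"] == pytest.approx(1.0)

    def test_symmetric_bimodal_marginal_estimates_midpoint(self):
        axes = (np.array([0.0, 0.5, 1.0]),)
        lp = np.log(np.array([0.5, 1e-12, 0.5]))
        from scipy.special import logsumexp
        grid = PosteriorGrid(model="RW1", param_names=("alpha",), axes=axes,
                             log_posterior=lp, log_loglik=lp, log_cell=0.0,
                             log_norm=float(logsumexp(lp)))
        assert estimate_parameters(grid)["alpha"] == pytest.approx(0.5, abs=1e-9)

    def test_random_model_has_no_grid(self, rw3_session, priors):
        with pytest.raises(ConfigError):
            evaluate_posterior_grid(rw3_session, "RANDOM", priors)


class TestFitSession:
    def test_random_model_fit(self):
        s = simulate_session("RANDOM", Params(), TaskConfig(n_trials=100), seed=1)
        fr = fit_session(s, "RANDOM")
        assert fr.max_loglik == pytest.approx(100 * math.log(0.5))
        assert fr.aic == pytest.approx(-2 * 100 * math.log(0.5))
        assert fr.bic == pytest.approx(-2 * 100 * math.log(0.5))
        assert fr.estimates == {}

    def test_deterministic(self, short_session, coarse_priors):
        a = fit_session(short_session, "RW3", coarse_priors)
        b = fit_session(short_session, "RW3", coarse_priors)
        assert a == b

    def test_estimates_within_grid_ranges(self, rw3_session, coarse_priors):
        fr = fit_session(rw3_session, "RW3", coarse_priors)
        for name, value in fr.estimates.items():
            ax = coarse_priors.axis(name)
            assert ax.lo <= value <= ax.hi
        assert fr.aic == pytest.approx(2 * 4 - 2 * fr.max_loglik)
        assert fr.bic == pytest.approx(-2 * fr.max_loglik + 4 * math.log(200))

    def test_empty_session_rejected(self, priors):
        with pytest.raises(DataError):
            fit_session(empty_session(), "RW1", priors)

    def test_recovery_rw1_500_trials(self, priors):
        """Median absolute error of the alpha estimate stays within 0.15."""
        errors = []
        task = TaskConfig(n_trials=500)
        for seed in range(20):
            s = simulate_session("RW1", Params(alpha=0.7, beta=4.0), task, seed=seed)
            errors.append(abs(fit_session(s, "RW1", priors).estimates["alpha"] - 0.7))
        assert np.median(errors) <= 0.15

    def test_shrinkage_toward_prior_on_short_sessions(self, priors):
        """Estimates from 20-trial sessions sit closer to the prior mean than
        estimates from 500-trial sessions of the same extreme agent."""
        agent = Params(alpha=0.95, beta=8.0)
        prior_mean = 0.5
        gaps = {20: [], 500: []}
        for T in gaps:
            for seed in range(10):
                s = simulate_session("RW1", agent, TaskConfig(n_trials=T), seed=seed)
                est = fit_session(s, "RW1", priors).estimates["alpha"]
                gaps[T].append(abs(est - prior_mean))
        assert np.mean(gaps[20]) < np.mean(gaps[500])

    def test_grid_refinement_stability(self, rw3_session):
        """Doubling every axis resolution moves estimates by < 0.02."""
        base = PriorSpec()
        fine = PriorSpec(grids={k: ax.refined(2) for k, ax in base.grids.items()})
        a = fit_session(rw3_session, "RW2", base).estimates
        b = fit_session(rw3_session, "RW2", fine).estimates
        for name in a:
            assert abs(a[name] - b[name]) < 0.02
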