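"""Priors, log posterior and the Metropolis-Hastings sampler."""

import numpy as np
import pandas as pd
import pytest

import gembayes as gb
from gembayes.bayes import PriorSpec, build_ld_prior, log_posterior, run_mh, split_rhat
from gembayes.pseudolik import ParameterSpace, PseudoLikelihood, fit_pseudo_mle


@pytest.fixture(scope="module")
def fitted(small_gem_data):
    sc, data = small_gem_data
    mle = fit_pseudo_mle(data, sc.spec)
    return sc, data, mle


class TestPriorSpec:
    def test_default_shape(self):
        space = ParameterSpace(3)
        prior = PriorSpec.default(space)
        assert list(prior.mu_b.index) == space.risk_coefficient_names()
        assert np.allclose(np.diag(prior.sigma_b), 9.0)

    def test_rejects_non_pd_covariance(self):
        space = ParameterSpace(1)
        names = space.risk_coefficient_names()
        bad = pd.DataFrame(-np.eye(len(names)), index=names, columns=names)
        with pytest.raises(ValueError):
            PriorSpec(mu_b=pd.Series(0.0, index=names), sigma_b=bad)


class TestLogPosterior:
    def test_out_of_support_is_minus_inf(self, fitted):
        sc, data, mle = fitted
        pl = PseudoLikelihood(data, sc.spec)
        space = mle.space
        prior = PriorSpec.default(space)
        theta = mle.estimates.to_numpy().copy()
        theta[space.index["eta"]] = 1.2
        assert log_posterior(theta, pl, space, prior) == -np.inf

    def test_additivity(self, fitted):
        """Posterior difference between two points = likelihood difference
        plus prior difference."""
        sc, data, mle = fitted
        pl = PseudoLikelihood(data, sc.spec)
        space = mle.space
        prior = PriorSpec.default(space)
        t1 = mle.estimates.to_numpy()
        t2 = t1.copy()
        t2[space.index["beta_x"]] += 0.3
        lp_diff = log_posterior(t2, pl, space, prior) - log_posterior(t1, pl, space, prior)
        ll_diff = pl.loglik_natural(t2, space) - pl.loglik_natural(t1, space)
        pr_diff = prior.log_density(pd.Series(t2, index=space.names)) - prior.log_density(
            pd.Series(t1, index=space.names)
        )
        assert lp_diff == pytest.approx(ll_diff + pr_diff, abs=1e-8)

    def test_flat_prior_argmax_is_pseudo_mle(self, fitted):
        """With an extremely diffuse prior the posterior mode coincides with
        the pseudo-MLE up to optimizer tolerance."""
        from scipy.optimize import minimize

        sc, data, mle = fitted
        pl = PseudoLikelihood(data, sc.spec)
        space = mle.space
        prior = PriorSpec.default(space, sd=1e4)
        u0 = space.to_unconstrained(mle.estimates.to_numpy()) + 0.05

        def neg(u):
            lp = log_posterior(space.to_natural(u), pl, space, prior)
            return -lp if np.isfinite(lp) else 1e12

        res = minimize(neg, u0, method="BFGS", options={"maxiter": 600})
        theta = space.to_natural(res.x)
        np.testing.assert_allclose(
            theta, mle.estimates.to_numpy(), atol=5e-3
        )


class TestLDPrior:
    def test_equilibrium_gives_diagonal(self):
        space = ParameterSpace(3)
        panel = gb.MarkerPanel(np.full(3, 0.25))
        prior = build_ld_prior(panel, space)
        s = prior.sigma_b.to_numpy()
        np.testing.assert_allclose(s, np.diag(np.diag(s)), atol=1e-12)

    def test_ld_structure_and_pd(self, three_marker_panel):
        space = ParameterSpace(3)
        prior = build_ld_prior(three_marker_panel, space, scale=3.0)
        s = prior.sigma_b.to_numpy()
        assert np.all(np.linalg.eigvalsh(s) > 0)
        # additive block off-diagonals follow V_A proportionally
        va = gb.coding_moments(three_marker_panel)["V_A"]
        got = prior.sigma_b.loc["beta_a1", "beta_a2"] / prior.sigma_b.loc["beta_a1", "beta_a1"]
        assert got == pytest.approx(va[0, 1] / va[0, 0])


class TestSampler:
    def test_same_seed_identical_draws(self, fitted):
        sc, data, mle = fitted
        prior = PriorSpec.default(mle.space)
        kw = dict(n_iter=400, burn_in=100, seed=5, init=mle)
        c1 = run_mh(data, prior, sc.spec, **kw)
        c2 = run_mh(data, prior, sc.spec, **kw)
        assert np.array_equal(c1.draws.to_numpy(), c2.draws.to_numpy())
        assert 0 < c1.acceptance_rate < 1

    def test_draws_respect_supports(self, fitted):
        sc, data, mle = fitted
        chain = run_mh(data, PriorSpec.default(mle.space), sc.spec,
                       n_iter=600, burn_in=200, seed=3, init=mle)
        assert chain.draws["eta"].between(0, 1).all()
        for j in (1, 2, 3):
            assert chain.draws[f"p_m{j}"].between(0, 1).all()

    def test_tight_prior_dominates(self, fitted):
        """A tight prior pulls every risk coefficient toward its mean and
        caps the posterior spread near the prior scale."""
        sc, data, mle = fitted
        space = mle.space
        names = space.risk_coefficient_names()
        prior = PriorSpec(
            mu_b=pd.Series(0.25, index=names),
            sigma_b=pd.DataFrame(np.eye(len(names)) * 0.05**2, index=names, columns=names),
        )
        chain = run_mh(data, prior, sc.spec, n_iter=4000, burn_in=1500, seed=9, init=mle)
        post_mean = chain.summaries["mean"]
        for n in names:
            if abs(mle.estimates[n] - 0.25) > 0.1:
                assert abs(post_mean[n] - 0.25) < abs(mle.estimates[n] - 0.25), n
        assert (chain.summaries.loc[names, "sd"] < 0.12).all()

    def test_zero_init_supported(self, fitted):
        sc, data, mle = fitted
        chain = run_mh(data, PriorSpec.default(mle.space), sc.spec,
                       n_iter=300, burn_in=100, seed=1,
                       init=np.zeros(mle.space.n_params))
        assert len(chain.draws) == 200

    def test_n_iter_must_exceed_burn_in(self, fitted):
        sc, data, mle = fitted
        with pytest.raises(ValueError):
            run_mh(data, PriorSpec.default(mle.space), sc.spec,
                   n_iter=100, burn_in=100, init=mle)


def test_default_length_chain_is_stationary(small_gem_data):
    """At the default chain length the split-Rhat diagnostic stays below
    1.05 for every parameter."""
    sc, data = small_gem_data
    mle = fit_pseudo_mle(data, sc.spec)
    chain = run_mh(data, PriorSpec.default(mle.space), sc.spec,
                   n_iter=20000, burn_in=5000, seed=2, init=mle)
    assert chain.rhat().max() < 1.05


def test_split_rhat_near_one_for_iid():
    rng = np.random.default_rng(0)
    assert split_rhat(rng.standard_normal(4000)) == pytest.approx(1.0, abs=0.05)
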