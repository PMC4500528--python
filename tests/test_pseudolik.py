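"""The retrospective pseudolikelihood: normalization, oracles, fitting."""

import itertools

import numpy as np
import pandas as pd
import pytest

import gembayes as gb
from gembayes.errors import ExposureModel, MisclassSpec
from gembayes.pseudolik import (
    CaseControlData,
    ParameterSpace,
    PseudoLikelihood,
    fit_naive,
    fit_pseudo_mle,
    log_pseudolik_obs,
)
from gembayes.risk import StudyDesign


def _triple_loop_log_pseudolik(d, g, x, params, eta, spec, panel):
    """Deliberately naive reference: explicit loops, direct exponentials."""
    _, pg = gb.joint_genotype_distribution(panel)
    pt = {0: 1 - eta, 1: eta}

    def s(k, gval, t):
        a = gval - 1.0
        p, q = panel.p_m[0], 1 - panel.p_m[0]
        b = {2: -q * q, 1: p * q, 0: -p * p}[gval]
        m = (params.beta_t[0] * t + params.beta_a[0, 0] * a
             + params.beta_at[0, 0] * t * a)
        if params.model_kind == gb.GEM:
            m += params.beta_d[0, 0] * b + params.beta_dt[0, 0] * t * b
        num = 1.0 if k == 0 else np.exp(params.kappa[0] + m)
        return num / (1.0 + np.exp(params.beta0[0] + m)) * pg[gval]

    def pm(xv, t):
        return ((xv * spec.xi1 + (1 - xv) * (1 - spec.xi1)) * (1 - t)
                + (xv * (1 - spec.xi0) + (1 - xv) * spec.xi0) * t)

    numer = sum(s(d, g, t) * pm(x, t) * pt[t] for t in (0, 1))
    denom = sum(s(k, gv, t) * pt[t]
                for k in (0, 1) for gv in (0, 1, 2) for t in (0, 1))
    return np.log(numer) - np.log(denom)


class TestNormalization:
    def test_sums_to_one_over_outcome_space(self, single_marker_scenario):
        """exp(log L) is a probability over (D, G, X): enumeration sums to 1."""
        sc = single_marker_scenario
        total = 0.0
        for d, gval, x in itertools.product((0, 1), (0, 1, 2), (0, 1)):
            total += np.exp(
                log_pseudolik_obs(d, [gval], x, None, sc.params,
                                  ExposureModel(eta=sc.eta), sc.spec, sc.panel)
            )
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_error_free_case_collapses_latent_sum(self, single_marker_scenario):
        sc = single_marker_scenario
        spec0 = MisclassSpec(0.0, 0.0)
        eta_model = ExposureModel(eta=sc.eta)
        # with xi = 0, X carries exactly the information of T
        ll = log_pseudolik_obs(1, [1], 1, None, sc.params, eta_model, spec0, sc.panel)
        # manual: numerator has only the t = x term
        ref = _triple_loop_log_pseudolik(1, 1, 1, sc.params, sc.eta, spec0, sc.panel)
        assert ll == pytest.approx(ref, abs=1e-12)

    def test_fully_missing_genotype_is_coding_free(self, single_marker_scenario):
        """With every marker missing the contribution marginalizes the
        genotype away entirely."""
        sc = single_marker_scenario
        eta_model = ExposureModel(eta=sc.eta)
        ll_missing = log_pseudolik_obs(1, [gb.MISSING], 1, None, sc.params,
                                       eta_model, sc.spec, sc.panel)
        # marginal over g computed by hand from the complete-data values
        vals = [np.exp(log_pseudolik_obs(1, [gv], 1, None, sc.params,
                                         eta_model, sc.spec, sc.panel))
                for gv in (0, 1, 2)]
        assert ll_missing == pytest.approx(np.log(sum(vals)), abs=1e-10)


class TestOracleEquivalence:
    def test_vectorized_equals_triple_loop(self, single_marker_scenario):
        """n=50 single-marker subjects: vectorized log pseudolikelihood equals
        the naive loop implementation within 1e-10."""
        sc = single_marker_scenario
        rng = np.random.default_rng(42)
        data = gb.simulate_case_control(sc, rng=rng)
        sub = CaseControlData(d=data.d[:50], x=data.x[:50], g=data.g[:50])
        pl = PseudoLikelihood(sub, sc.spec)
        eta_model = ExposureModel(eta=sc.eta)
        vec = pl.per_subject(sc.params, eta_model, sc.panel)
        ref = np.array([
            _triple_loop_log_pseudolik(sub.d[i], int(sub.g[i, 0]), sub.x[i],
                                       sc.params, sc.eta, sc.spec, sc.panel)
            for i in range(50)
        ])
        np.testing.assert_allclose(vec, ref, atol=1e-10)

    def test_fast_path_equals_generic_path(self, small_gem_data):
        sc, data = small_gem_data
        pl = PseudoLikelihood(data, sc.spec)
        space = ParameterSpace(3)
        theta = sc.true_theta().to_numpy()
        fast = pl.loglik_natural(theta, space)
        generic = pl.loglik_natural(theta, space, method="generic")
        assert fast == pytest.approx(generic, abs=1e-8)

    def test_fast_path_equals_generic_with_missing_genotypes(self):
        sc = gb.experiment1_scenario(n_cases=150, n_controls=150, missing_rate=0.5)
        data = gb.simulate_case_control(sc, rng=7)
        pl = PseudoLikelihood(data, sc.spec)
        space = ParameterSpace(3)
        theta = sc.true_theta().to_numpy()
        assert pl.loglik_natural(theta, space) == pytest.approx(
            pl.loglik_natural(theta, space, method="generic"), abs=1e-8
        )


class TestParameterSpace:
    def test_pack_unpack_round_trip(self, exp1_scenario):
        space = ParameterSpace(3)
        theta = exp1_scenario.true_theta().to_numpy()
        params, eta_model, panel = space.unpack(theta, exp1_scenario.design)
        back = space.pack(params, eta_model, panel)
        np.testing.assert_allclose(back, theta, atol=1e-12)

    def test_transform_round_trip(self, exp1_scenario):
        space = ParameterSpace(3)
        theta = exp1_scenario.true_theta().to_numpy()
        u = space.to_unconstrained(theta)
        np.testing.assert_allclose(space.to_natural(u), theta, atol=1e-9)

    def test_transformed_delta_respects_feasibility_box(self):
        space = ParameterSpace(2)
        u = np.zeros(space.n_params)
        u[space.index["delta12"]] = 50.0  # extreme unconstrained value
        u[space.index["p_m1"]] = 0.0
        u[space.index["p_m2"]] = 0.0
        theta = space.to_natural(u)
        p = np.array([theta[space.index["p_m1"]], theta[space.index["p_m2"]]])
        hi = min(p[0] * (1 - p[1]), (1 - p[0]) * p[1])
        assert theta[space.index["delta12"]] <= hi + 1e-12


class TestFitting:
    def test_score_vanishes_at_optimum(self, small_gem_data):
        sc, data = small_gem_data
        fit = fit_pseudo_mle(data, sc.spec, compute_vcov=False)
        assert fit.converged
        assert fit.grad_norm < 0.05

    def test_vcov_is_symmetric_psd(self, small_gem_data):
        sc, data = small_gem_data
        fit = fit_pseudo_mle(data, sc.spec)
        v = fit.vcov.to_numpy()
        np.testing.assert_allclose(v, v.T, atol=1e-10)
        assert np.all(np.linalg.eigvalsh(v) > -1e-8)

    def test_design_count_scaling_invariance(self, single_marker_scenario):
        """Multiplying all n_d by a constant changes only kappa, by the
        sampling-fraction identity."""
        sc = single_marker_scenario
        data = gb.simulate_case_control(sc, rng=3)
        fit1 = fit_pseudo_mle(data, sc.spec, compute_vcov=False)
        # same subjects, design counts scaled by 3 (pi unchanged)
        data3 = CaseControlData(
            d=np.tile(data.d, 3), x=np.tile(data.x, 3), g=np.tile(data.g, (3, 1)),
            design=StudyDesign(data.design.n_d * 3, pi=data.design.pi),
        )
        fit3 = fit_pseudo_mle(data3, sc.spec, compute_vcov=False)
        for name in fit1.estimates.index:
            if name == "kappa":
                continue
            assert fit3.estimates[name] == pytest.approx(
                fit1.estimates[name], abs=5e-3
            ), name
        # kappa shifts by log(3)-log(3) = 0 here since both strata scale equally;
        # tripling only the cases instead shifts kappa by log 3
        data_cases = CaseControlData(
            d=np.concatenate([data.d, np.ones(2 * (data.d == 1).sum(), int)]),
            x=np.concatenate([data.x, np.tile(data.x[data.d == 1], 2)]),
            g=np.vstack([data.g, np.tile(data.g[data.d == 1], (2, 1))]),
            design=StudyDesign(
                [data.design.n_d[0], 3 * data.design.n_d[1]], pi=data.design.pi
            ),
        )
        fit_c = fit_pseudo_mle(data_cases, sc.spec, compute_vcov=False)
        assert fit_c.estimates["kappa"] - fit1.estimates["kappa"] == pytest.approx(
            np.log(3.0), abs=0.15
        )

    def test_error_free_data_matches_error_free_fit(self, single_marker_scenario):
        """Generated and fitted with xi=0, the pseudo-MLE is the nested
        error-free model's fit: X is treated exactly as T."""
        from dataclasses import replace

        sc = replace(single_marker_scenario, spec=MisclassSpec(0.0, 0.0))
        data = gb.simulate_case_control(sc, rng=11)
        fit = fit_pseudo_mle(data, MisclassSpec(0.0, 0.0), compute_vcov=False)
        assert fit.converged
        # eta estimate must match the observed exposure frequency in the
        # denominator-weighted sense; sanity bound only
        assert abs(fit.estimates["eta"] - sc.eta) < 0.2


class TestCovariates:
    def test_fit_with_binary_covariate(self, small_aem_data):
        """A noise covariate Z enters linearly: the fit converges and its
        coefficient lands near zero."""
        sc, base = small_aem_data
        rng = np.random.default_rng(17)
        z = rng.integers(0, 2, size=base.n).astype(float)[:, None]
        data = CaseControlData(d=base.d, x=base.x, g=base.g, z=z,
                               design=base.design)
        fit = fit_pseudo_mle(data, sc.spec, model_kind=gb.AEM,
                             compute_vcov=False)
        assert fit.converged
        assert abs(fit.estimates["beta_z1"]) < 0.6
        # the covariate-conditional evaluation still normalizes per subject
        pl = PseudoLikelihood(data, sc.spec, model_kind=gb.AEM)
        ll = pl.per_subject_natural(fit.estimates.to_numpy(), fit.space)
        assert np.all(ll < 0)

    def test_log_pseudolik_obs_accepts_z(self, small_aem_data):
        sc, base = small_aem_data
        from dataclasses import replace as dc_replace

        params = dc_replace(sc.params, beta_z=np.array([[0.2]]),
                            beta_az=np.zeros((1, 3)))
        ll0 = log_pseudolik_obs(1, base.g[0], 1, [0.0], params,
                                ExposureModel(eta=sc.eta), sc.spec, sc.panel)
        ll1 = log_pseudolik_obs(1, base.g[0], 1, [1.0], params,
                                ExposureModel(eta=sc.eta), sc.spec, sc.panel)
        assert np.isfinite(ll0) and np.isfinite(ll1)
        assert ll0 != ll1


class TestNaive:
    def test_attenuation_sign(self, small_gem_data):
        """Under nondifferential misclassification the naive exposure effect
        is biased toward zero."""
        sc, data = small_gem_data
        fit = fit_naive(data)
        assert fit.converged
        assert abs(fit.estimates["beta_x"]) < sc.params.beta_t[0]

    def test_reports_control_allele_frequencies(self, small_gem_data):
        sc, data = small_gem_data
        fit = fit_naive(data)
        controls = data.g[data.d == 0]
        expected = controls[controls[:, 0] >= 0, 0].mean() / 2
        assert fit.estimates["p_m1"] == pytest.approx(expected, abs=1e-9)
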