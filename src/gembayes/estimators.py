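"""Scikit-learn style estimators wrapping the pseudolikelihood machinery.

All estimators share the input convention ``fit(X, y)`` where ``y`` is the
disease status (0 = control) and ``X`` holds the observed exposure, optional
exactly measured covariates and the marker genotypes: either a DataFrame
(exposure column named by ``exposure_col``, covariate columns listed in
``covariate_cols``, every remaining column a marker with values 0/1/2/NaN)
or a plain array whose first column is the exposure and remaining columns
are markers.  Estimators are clonable, expose ``get_params``/``set_params``
and store fitted quantities in trailing-underscore attributes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import genotype as gt
from .errors import MisclassSpec
from .genotype import MISSING
from .pseudolik import CaseControlData, fit_naive, fit_pseudo_mle
from .risk import GEM, StudyDesign, linear_predictor

__all__ = ["NaiveLogisticGxE", "PseudoMLE", "PosteriorSampler", "AsymptoticPosterior"]


class _BaseGxE(BaseEstimator):
    """Shared input handling for the gene-environment estimators."""

    def _parse_X(self, X):
        if isinstance(X, pd.DataFrame):
            exposure_col = getattr(self, "exposure_col", "x")
            covariate_cols = list(getattr(self, "covariate_cols", None) or [])
            if exposure_col not in X.columns:
                raise ValueError(f"exposure column '{exposure_col}' not found")
            marker_cols = [
                c for c in X.columns if c != exposure_col and c not in covariate_cols
            ]
            x = X[exposure_col].to_numpy()
            g = X[marker_cols].to_numpy(dtype=float)
            z = X[covariate_cols].to_numpy(dtype=float) if covariate_cols else None
            return x, g, z
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] < 2:
            raise ValueError("X must be 2-D with an exposure column and markers")
        return arr[:, 0], arr[:, 1:], None

    def _build_data(self, X, y) -> CaseControlData:
        y = np.asarray(y, dtype=int)
        if isinstance(X, pd.DataFrame):
            exposure_col = getattr(self, "exposure_col", "x")
            covariate_cols = list(getattr(self, "covariate_cols", None) or [])
            if exposure_col not in X.columns:
                raise ValueError(f"exposure column '{exposure_col}' not found")
            marker_cols = [
                c for c in X.columns if c != exposure_col and c not in covariate_cols
            ]
            x = X[exposure_col].to_numpy()
            g = X[marker_cols].to_numpy(dtype=float)
            z = X[covariate_cols].to_numpy(dtype=float) if covariate_cols else None
            names = marker_cols
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim != 2 or arr.shape[1] < 2:
                raise ValueError("X must be 2-D with an exposure column and markers")
            x, g, z = arr[:, 0], arr[:, 1:], None
            names = [f"m{j+1}" for j in range(g.shape[1])]
        prevalence = getattr(self, "prevalence", None)
        design = None
        if prevalence is not None:
            counts = [(y == 0).sum(), (y == 1).sum()]
            design = StudyDesign(counts, pi=[prevalence])
        data = CaseControlData(d=y, x=x, g=g, z=z, design=design, marker_names=names)
        return data

    def _spec(self) -> MisclassSpec:
        return MisclassSpec(xi0=self.xi0, xi1=self.xi1)

    def _predict_proba_from(self, X, params, panel, design):
        """Prospective pr(D=1 | G, T=x, Z); missing markers are marginalized
        over the fitted genotype distribution."""
        x_obs, g_obs, z_obs = self._parse_X(X)
        g_obs = np.where(np.isnan(g_obs), MISSING, g_obs).astype(int)
        beta0 = params.beta0[0]
        states, pg = gt.joint_genotype_distribution(panel)
        a_states = states.astype(float) - 1.0
        b_states = gt._dominance_table(panel.p_m)[states, np.arange(panel.n_markers)]
        out = np.empty(len(x_obs))
        for i in range(len(x_obs)):
            gi = g_obs[i]
            obs = gi != MISSING
            compat = np.all(states[:, obs] == gi[obs], axis=1)
            w = pg[compat]
            w = w / w.sum()
            t = np.full(compat.sum(), float(x_obs[i]))
            z = None if z_obs is None else np.tile(z_obs[i], (compat.sum(), 1))
            m = linear_predictor(a_states[compat], b_states[compat], t, z, params)[:, 0]
            out[i] = float(w @ expit(beta0 + m))
        return out


class NaiveLogisticGxE(_BaseGxE):
    """Prospective logistic regression that ignores exposure misclassification.

    Regresses D on the observed exposure, genotype codes and their
    interactions, treating the error-prone X as the true exposure; the
    standard comparator whose exposure and interaction coefficients are
    attenuated under nondifferential misclassification.
    """

    def __init__(self, model_kind: str = GEM, exposure_col: str = "x", covariate_cols=None):
        self.model_kind = model_kind
        self.exposure_col = exposure_col
        self.covariate_cols = covariate_cols

    def fit(self, X, y):
        data = self._build_data(X, y)
        self.result_ = fit_naive(data, model_kind=self.model_kind)
        self.estimates_ = self.result_.estimates
        self.se_ = self.result_.se
        self.panel_ = self.result_.panel
        self.n_features_in_ = data.n_markers + 1
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "result_")
        # within-sample (retrospective) probability from the fitted logistic
        from .risk import RiskParams

        est = self.estimates_
        i = self.panel_.n_markers
        params = RiskParams(
            beta0=[est["kappa"]],
            kappa=[est["kappa"]],
            beta_t=[est["beta_x"]],
            beta_a=[[est[f"beta_a{j+1}"] for j in range(i)]],
            beta_at=[[est[f"beta_ax{j+1}"] for j in range(i)]],
            beta_d=[[est.get(f"beta_d{j+1}", 0.0) for j in range(i)]],
            beta_dt=[[est.get(f"beta_dx{j+1}", 0.0) for j in range(i)]],
            model_kind=self.model_kind,
        )
        p1 = self._predict_proba_from(X, params, self.panel_, None)
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class PseudoMLE(_BaseGxE):
    """Pseudo-maximum-likelihood estimator of the misclassification-corrected
    gene-environment interaction model.

    Maximizes the retrospective pseudolikelihood over the risk coefficients,
    the exposure prevalence eta and the genotype-distribution parameters
    (allele frequencies and pairwise LD), with the misclassification
    probabilities (xi0, xi1) treated as known.

    Parameters
    ----------
    model_kind : {'gem', 'aem'}
        Genotype effect model (additive + dominance) or additive-only model.
    xi0, xi1 : float
        pr(X=0|T=1) and pr(X=1|T=0).
    prevalence : float or None
        Population disease prevalence; when given, the intercept is recovered
        from the retrospective offset kappa through the sampling identity.
    """

    def __init__(
        self,
        model_kind: str = GEM,
        xi0: float = 0.0,
        xi1: float = 0.0,
        prevalence: float | None = None,
        gtol: float = 1e-8,
        maxiter: int = 1000,
        compute_vcov: bool = True,
        exposure_col: str = "x",
        covariate_cols=None,
    ):
        self.model_kind = model_kind
        self.xi0 = xi0
        self.xi1 = xi1
        self.prevalence = prevalence
        self.gtol = gtol
        self.maxiter = maxiter
        self.compute_vcov = compute_vcov
        self.exposure_col = exposure_col
        self.covariate_cols = covariate_cols

    def fit(self, X, y):
        data = self._build_data(X, y)
        self.result_ = fit_pseudo_mle(
            data,
            self._spec(),
            model_kind=self.model_kind,
            pi_known=self.prevalence is not None,
            gtol=self.gtol,
            maxiter=self.maxiter,
            compute_vcov=self.compute_vcov,
        )
        self.estimates_ = self.result_.estimates
        self.se_ = self.result_.se
        self.vcov_ = self.result_.vcov
        self.loglik_ = self.result_.loglik
        self.converged_ = self.result_.converged
        self.params_ = self.result_.params
        self.panel_ = self.result_.panel
        self.eta_ = self.result_.eta_model.eta
        self.n_features_in_ = data.n_markers + 1
        self._design = data.design
        return self

    def predict_proba(self, X):
        """Population (prospective) pr(D | G, T=x) at the fitted parameters.

        Interprets the exposure column of ``X`` as the *true* exposure.
        Requires a known prevalence so the intercept is identified.
        """
        check_is_fitted(self, "result_")
        if self.prevalence is None:
            raise ValueError("predict_proba requires prevalence (intercept identification)")
        p1 = self._predict_proba_from(X, self.params_, self.panel_, self._design)
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class PosteriorSampler(_BaseGxE):
    """Metropolis-Hastings sampler for the pseudolikelihood-based posterior.

    A normal prior (default N(0, prior_sd^2 I), optionally LD-structured) is
    placed on the risk coefficients, uniform(0,1) priors on the exposure
    prevalence and allele frequencies.  ``fit`` runs the adaptive
    random-walk chain initialized at the pseudo-MLE (or zeros) and stores
    posterior means as the point estimates.
    """

    def __init__(
        self,
        model_kind: str = GEM,
        xi0: float = 0.0,
        xi1: float = 0.0,
        prevalence: float | None = None,
        prior_sd: float = 3.0,
        prior_mean: float = 0.0,
        ld_prior: bool = False,
        n_iter: int = 20000,
        burn_in: int = 5000,
        seed: int = 0,
        init: str = "mle",
        exposure_col: str = "x",
        covariate_cols=None,
    ):
        self.model_kind = model_kind
        self.xi0 = xi0
        self.xi1 = xi1
        self.prevalence = prevalence
        self.prior_sd = prior_sd
        self.prior_mean = prior_mean
        self.ld_prior = ld_prior
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.seed = seed
        self.init = init
        self.exposure_col = exposure_col
        self.covariate_cols = covariate_cols

    def fit(self, X, y):
        from .bayes import PriorSpec, build_ld_prior, run_mh

        data = self._build_data(X, y)
        spec = self._spec()
        mle = fit_pseudo_mle(
            data, spec, model_kind=self.model_kind,
            pi_known=self.prevalence is not None,
        )
        space = mle.space
        if self.ld_prior:
            prior = build_ld_prior(mle.panel, space, scale=self.prior_sd)
        else:
            prior = PriorSpec.default(space, sd=self.prior_sd, mean=self.prior_mean)
        init = mle if self.init == "mle" else np.zeros(space.n_params)
        self.chain_ = run_mh(
            data,
            prior,
            spec,
            model_kind=self.model_kind,
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            seed=self.seed,
            init=init,
            pi_known=self.prevalence is not None,
        )
        self.mle_ = mle
        self.prior_ = prior
        self.draws_ = self.chain_.draws
        self.summaries_ = self.chain_.summaries
        self.acceptance_rate_ = self.chain_.acceptance_rate
        self.estimates_ = self.chain_.summaries["mean"]
        self.se_ = self.chain_.summaries["sd"]
        self.n_features_in_ = data.n_markers + 1
        return self


class AsymptoticPosterior(_BaseGxE):
    """Gaussian large-sample approximation of the posterior.

    Combines the pseudo-MLE (with its sandwich covariance as the data
    precision) with the normal prior precision on the risk coefficients:
    precision-weighted mean and summed precision, the low-cost alternative
    to MCMC for large samples.
    """

    def __init__(
        self,
        model_kind: str = GEM,
        xi0: float = 0.0,
        xi1: float = 0.0,
        prevalence: float | None = None,
        prior_sd: float = 3.0,
        prior_mean: float = 0.0,
        flat_prior: bool = False,
        exposure_col: str = "x",
        covariate_cols=None,
    ):
        self.model_kind = model_kind
        self.xi0 = xi0
        self.xi1 = xi1
        self.prevalence = prevalence
        self.prior_sd = prior_sd
        self.prior_mean = prior_mean
        self.flat_prior = flat_prior
        self.exposure_col = exposure_col
        self.covariate_cols = covariate_cols

    def fit(self, X, y):
        from .asymptotic import asymptotic_posterior
        from .bayes import PriorSpec

        data = self._build_data(X, y)
        spec = self._spec()
        mle = fit_pseudo_mle(
            data, spec, model_kind=self.model_kind,
            pi_known=self.prevalence is not None,
        )
        prior = None if self.flat_prior else PriorSpec.default(
            mle.space, sd=self.prior_sd, mean=self.prior_mean
        )
        self.result_ = asymptotic_posterior(
            data, prior, spec, model_kind=self.model_kind, mle=mle
        )
        self.mle_ = mle
        self.mean_ = self.result_.mean
        self.cov_ = self.result_.cov
        self.estimates_ = self.result_.mean
        self.se_ = self.result_.se
        self.n_features_in_ = data.n_markers + 1
        return self

    def credible_interval(self, name: str, level: float = 0.90):
        check_is_fitted(self, "result_")
        return self.result_.interval(name, level)
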