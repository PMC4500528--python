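"""Gaussian large-sample approximation of the pseudolikelihood posterior.

The posterior of the parameter vector is approximately normal with precision
equal to the data precision plus the prior precision,

    Sigma_n = (I_n + J)^{-1},
    M_n     = Sigma_n (I_n theta_hat + J theta_0),

where theta_hat is the pseudo-MLE, theta_0 the prior mode, J minus the
Hessian of the log prior, and I_n the data precision.  Under retrospective
sampling the score variance requires the case-control correction

    Lambda = sum_d (n_d / n) E(Psi | D = d) E(Psi | D = d)^T,

and the per-observation information can be estimated either from the
Hessian of the total log pseudolikelihood or from the moment identity
Sigma_hat + Lambda_hat.  The sample-size convention here makes the
flat-prior covariance coincide with the sandwich covariance of the
pseudo-MLE, so a flat prior reproduces frequentist pseudo-MLE inference
exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MisclassSpec
from .pseudolik import (
    CaseControlData,
    FitResult,
    ParameterSpace,
    PseudoLikelihood,
    _gradient,
    _hessian,
    _jacobian,
    _robust_inv,
    fit_pseudo_mle,
    sandwich_vcov,
)
from .risk import GEM

__all__ = [
    "AsymptoticPosteriorResult",
    "score_matrix",
    "lambda_correction",
    "information_estimates",
    "asymptotic_posterior",
]


@dataclass
class AsymptoticPosteriorResult:
    """Normal posterior approximation N(mean, cov) with audit pieces."""

    mean: pd.Series
    cov: pd.DataFrame
    data_precision: np.ndarray
    prior_precision: np.ndarray
    lambda_hat: np.ndarray
    sigma_hat: np.ndarray
    info_hessian: np.ndarray
    info_moment: np.ndarray
    mle: FitResult

    @property
    def se(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.clip(np.diag(self.cov.to_numpy()), 0, None)),
            index=self.mean.index,
        )

    def interval(self, name: str, level: float = 0.90) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        m, s = self.mean[name], self.se[name]
        return (m - z * s, m + z * s)


def score_matrix(
    pl: PseudoLikelihood, theta: np.ndarray, space: ParameterSpace, step: float = 1e-5
) -> np.ndarray:
    """Per-subject score vectors Psi_i (central differences, natural scale).

    At the pseudo-MLE the column means vanish up to optimizer tolerance.
    Parameters must lie in the interior of the support.
    """
    theta = np.asarray(theta, dtype=float)
    named = pd.Series(theta, index=space.names)
    for name in space.names:
        if name == "eta" or name.startswith("p_m"):
            if not (1e-6 < named[name] < 1 - 1e-6):
                raise ValueError(f"{name} is on the boundary of its support")
    return _jacobian(lambda th: pl.per_subject_natural(th, space), theta, step=step)


def lambda_correction(scores: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Case-control correction sum_d (n_d/n) mean_d(Psi) mean_d(Psi)^T."""
    scores = np.asarray(scores, dtype=float)
    d = np.asarray(d)
    n = scores.shape[0]
    cats, counts = np.unique(d, return_counts=True)
    if np.any(counts == 0):
        raise ValueError("empty disease stratum")
    lam = np.zeros((scores.shape[1], scores.shape[1]))
    for k, nk in zip(cats, counts, strict=True):
        mu = scores[d == k].mean(axis=0)
        lam += (nk / n) * np.outer(mu, mu)
    return lam


def information_estimates(
    pl: PseudoLikelihood, theta_hat: np.ndarray, space: ParameterSpace
) -> dict[str, np.ndarray]:
    """Both per-observation information estimators: Hessian- and moment-based."""
    n = pl.data.n
    hess = _hessian(lambda th: pl.loglik_natural(th, space), theta_hat)
    info_hess = -(hess + hess.T) / 2.0 / n
    psi = score_matrix(pl, theta_hat, space)
    sigma_hat = (psi - psi.mean(axis=0)).T @ (psi - psi.mean(axis=0)) / n
    lam = lambda_correction(psi, pl.data.d)
    return {
        "hessian": info_hess,
        "moment": sigma_hat + lam,
        "Sigma": sigma_hat,
        "Lambda": lam,
        "scores": psi,
    }


def asymptotic_posterior(
    data: CaseControlData,
    prior,
    spec: MisclassSpec,
    model_kind: str = GEM,
    mle: FitResult | None = None,
    ridge: float = 1e-8,
) -> AsymptoticPosteriorResult:
    """Normal approximation to the pseudolikelihood posterior.

    ``prior`` is a :class:`~gembayes.bayes.PriorSpec`; its normal block on
    the risk coefficients contributes prior precision (uniform/flat blocks
    contribute none) and its mode supplies theta_0.  With an everywhere-flat
    prior the returned mean equals the pseudo-MLE and the covariance its
    sandwich covariance.
    """
    if mle is None:
        mle = fit_pseudo_mle(data, spec, model_kind=model_kind)
    space = mle.space
    pl = PseudoLikelihood(data, spec, model_kind=model_kind)
    theta_hat = mle.estimates.to_numpy()
    vcov, pieces = sandwich_vcov(pl, theta_hat, space, return_pieces=True)
    info = information_estimates(pl, theta_hat, space)
    data_prec = _robust_inv(vcov)
    p = space.n_params
    prior_prec = np.zeros((p, p))
    theta0 = theta_hat.copy()  # flat directions: prior mode defaults to the MLE
    if prior is not None:
        names = list(prior.mu_b.index)
        idx = [space.index[n] for n in names]
        block = _robust_inv(prior.sigma_b.to_numpy())
        for a, ia in enumerate(idx):
            theta0[ia] = prior.mu_b.iloc[a]
            for b, ib in enumerate(idx):
                prior_prec[ia, ib] = block[a, b]
    total = data_prec + prior_prec
    try:
        cov = np.linalg.inv(total)
    except np.linalg.LinAlgError:
        warnings.warn("singular posterior precision; applying ridge regularization")
        cov = np.linalg.inv(total + ridge * np.eye(p))
    cov = (cov + cov.T) / 2.0
    mean = cov @ (data_prec @ theta_hat + prior_prec @ theta0)
    return AsymptoticPosteriorResult(
        mean=pd.Series(mean, index=space.names),
        cov=pd.DataFrame(cov, index=space.names, columns=space.names),
        data_precision=data_prec,
        prior_precision=prior_prec,
        lambda_hat=info["Lambda"],
        sigma_hat=info["Sigma"],
        info_hessian=info["hessian"],
        info_moment=info["moment"],
        mle=mle,
    )
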