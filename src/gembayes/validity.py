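"""Posterior-coverage validity check of the pseudolikelihood.

A likelihood-like criterion is "coverage proper" if one-sided posterior
credible sets attain their nominal coverage when the truth is drawn from the
prior.  Numerically: draw tau_k from the prior, simulate data under tau_k,
form the posterior, and record H_k, the posterior CDF evaluated at tau_k.
Under a coverage-proper likelihood the H_k are uniform(0,1); a
Kolmogorov-Smirnov test that rejects uniformity for some prior invalidates
the criterion.  Because the check can only invalidate, a battery of
scenarios that fails to reject is taken as evidence of validity.

Two analytic controls are shipped: a conjugate Beta-binomial model (proper
by construction, H exactly uniform) and a temperature-corrupted version of
it (likelihood raised to a power != 1) whose H statistics are detectably
non-uniform — the positive and negative controls for the machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bayes import PriorSpec, run_mh
from .simulate import Scenario, simulate_case_control

__all__ = [
    "ValidityReport",
    "h_from_draws",
    "coverage_check",
    "conjugate_coverage_check",
]


@dataclass
class ValidityReport:
    """H statistics with their KS uniformity test, per monitored parameter."""

    h: pd.DataFrame  # columns = monitored parameters, one row per replicate
    ks_stat: pd.Series
    ks_p: pd.Series
    seed: int
    n_failed: int = 0
    scenario: dict = field(default_factory=dict)

    def rejects(self, alpha: float = 0.05) -> pd.Series:
        return self.ks_p < alpha


def h_from_draws(draws: np.ndarray, tau: float) -> float:
    """Posterior CDF at tau from chain draws, mid-rank (r + 0.5)/N convention.

    The mid-rank convention avoids exact 0/1 values and is invariant under
    monotone reparameterization of the monitored scalar.
    """
    v = np.asarray(draws, dtype=float)
    r = np.sum(v < tau) + 0.5 * np.sum(v == tau)
    return float((r + 0.5) / (v.size + 1))


def _ks_uniform(h: np.ndarray) -> tuple[float, float]:
    res = stats.kstest(h, "uniform")
    return float(res.statistic), float(res.pvalue)


def coverage_check(
    scenario: Scenario,
    prior_sd: float,
    parameters: list[str],
    m: int = 100,
    seed: int = 0,
    mcmc_options: dict | None = None,
    prior_mean: float = 0.0,
) -> ValidityReport:
    """Monahan-Boos coverage check of the pseudolikelihood posterior.

    For k = 1..m: draw the monitored risk coefficients from their
    N(prior_mean, prior_sd^2) prior, regenerate a case-control sample under
    those values (remaining generative parameters fixed at the scenario's),
    sample the posterior by Metropolis-Hastings under the same prior, and
    record H_k = posterior CDF at the drawn truth.  Nonconvergent replicates
    (pathological acceptance) are excluded and counted.
    """
    from dataclasses import replace as dc_replace

    from .pseudolik import ParameterSpace
    from .simulate import make_scenario

    if m < 50:
        raise ValueError("m must be at least 50 for a meaningful KS test")
    mcmc_options = dict(
        {"n_iter": 3000, "burn_in": 1000}, **(mcmc_options or {})
    )
    rng = np.random.default_rng(seed)
    space = scenario.true_space()
    for p in parameters:
        if p not in space.risk_coefficient_names():
            raise ValueError(f"{p} is not a risk coefficient of this model")
    rows, n_failed = [], 0
    for k in range(m):
        draw = {p: rng.normal(prior_mean, prior_sd) for p in parameters}
        params = scenario.params
        updates = {}
        for p, v in draw.items():
            if p == "beta_x":
                updates["beta_t"] = np.array([v])
            else:
                block = {"beta_a": "beta_a", "beta_ax": "beta_at", "beta_d": "beta_d", "beta_dx": "beta_dt"}[p[:-1]]
                arr = getattr(params, block).copy()
                arr[0, int(p[-1]) - 1] = v
                updates[block] = arr
        params_k = dc_replace(params, **updates)
        scen_k = make_scenario(
            scenario.panel,
            scenario.eta,
            scenario.spec,
            dc_replace(params_k, kappa=None),
            scenario.design,
            scenario.missing_rate,
        )
        data = simulate_case_control(scen_k, rng=rng)
        prior = PriorSpec.default(space, sd=prior_sd, mean=prior_mean)
        try:
            chain = run_mh(
                data,
                prior,
                scenario.spec,
                model_kind=scenario.model_kind,
                seed=int(rng.integers(2**31 - 1)),
                **mcmc_options,
            )
        except Exception:
            n_failed += 1
            continue
        if not (0.01 <= chain.acceptance_rate <= 0.99):
            n_failed += 1
            continue
        rows.append({p: h_from_draws(chain.draws[p].to_numpy(), draw[p]) for p in parameters})
    h = pd.DataFrame(rows)
    ks = {p: _ks_uniform(h[p].to_numpy()) for p in h.columns}
    return ValidityReport(
        h=h,
        ks_stat=pd.Series({p: s for p, (s, _) in ks.items()}),
        ks_p=pd.Series({p: v for p, (_, v) in ks.items()}),
        seed=seed,
        n_failed=n_failed,
        scenario={
            "prior_sd": prior_sd,
            "parameters": parameters,
            "m": m,
            "n_d": scenario.design.n_d.tolist(),
            "xi": (scenario.spec.xi0, scenario.spec.xi1),
        },
    )


def conjugate_coverage_check(
    m: int = 200,
    n_obs: int = 40,
    a: float = 2.0,
    b: float = 2.0,
    temperature: float = 1.0,
    seed: int = 0,
) -> ValidityReport:
    """Analytic Beta-binomial control for the H-statistic machinery.

    The truth tau ~ Beta(a, b); data Y ~ Binomial(n_obs, tau); the posterior
    under likelihood temperature ``c`` is Beta(a + c Y, b + c(n - Y)) so H_k
    is computed exactly.  ``temperature=1`` is the proper-Bayes positive
    control (H uniform); ``temperature != 1`` is the corrupted negative
    control whose H statistics the KS test should reject.
    """
    rng = np.random.default_rng(seed)
    tau = rng.beta(a, b, size=m)
    y = rng.binomial(n_obs, tau)
    h = stats.beta.cdf(tau, a + temperature * y, b + temperature * (n_obs - y))
    ks_stat, ks_p = _ks_uniform(h)
    return ValidityReport(
        h=pd.DataFrame({"tau": h}),
        ks_stat=pd.Series({"tau": ks_stat}),
        ks_p=pd.Series({"tau": ks_p}),
        seed=seed,
        scenario={"model": "beta-binomial", "temperature": temperature, "m": m, "n_obs": n_obs},
    )
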