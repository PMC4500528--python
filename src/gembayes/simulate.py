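"""Synthetic case-control data generator and bias/RMSE experiment runner.

The generator emulates the shipped study conditions: three markers with
allele-M frequency 0.25 in pairwise LD (Delta = 0.03), a Bernoulli(0.5) true
exposure, nondifferential misclassification pr(X=0|T=1) = 0.20 and
pr(X=1|T=0) = 0.25, a logistic disease model with marginal prevalence 0.005,
and equal numbers of cases and controls (1,500/1,500 for the large design,
350/350 for the small additive-model design).

Retrospective sampling draws cases and controls directly from the population
conditional laws pr(G, T | D = d); this is distribution-identical to
rejection-until-quota sampling of iid population subjects (the accepted
subjects of each stratum are iid draws from the conditional law), and a
rejection sampler is kept as a cross-checkable oracle.  The intercept beta_0
is calibrated by root finding so that the population prevalence matches the
target pi.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from . import genotype as gt
from .errors import ExposureModel, MisclassSpec
from .genotype import MISSING, MarkerPanel
from .pseudolik import CaseControlData, ParameterSpace
from .risk import AEM, GEM, RiskParams, StudyDesign, linear_predictor

__all__ = [
    "Scenario",
    "calibrate_beta0",
    "simulate_case_control",
    "run_experiment",
    "experiment1_scenario",
    "small_sample_scenario",
    "experiment2_scenario",
]


def _population_grid(panel: MarkerPanel, eta: float, params: RiskParams):
    """(state, t) grid with weights w = pr(g) pr(t) and case probabilities."""
    states, pg = gt.joint_genotype_distribution(panel)
    a = states.astype(float) - 1.0
    b = gt._dominance_table(panel.p_m)[states, np.arange(panel.n_markers)]
    rows_a = np.vstack([a, a])
    rows_b = np.vstack([b, b])
    t = np.concatenate([np.zeros(len(states)), np.ones(len(states))])
    w = np.concatenate([pg * (1 - eta), pg * eta])
    m = linear_predictor(rows_a, rows_b, t, None, params)[:, 0]
    return states, t.astype(int), w, m


def calibrate_beta0(
    params: RiskParams, panel: MarkerPanel, eta: float, pi: float
) -> float:
    """Intercept beta_0 giving population prevalence pi under the risk model."""
    _, _, w, m = _population_grid(panel, eta, params)

    def prev(b0):
        return float(w @ expit(b0 + m)) - pi

    lo, hi = -30.0, 10.0
    if prev(lo) > 0 or prev(hi) < 0:
        raise ValueError(f"target prevalence {pi} not attainable by any intercept")
    return float(brentq(prev, lo, hi, xtol=1e-12))


@dataclass(frozen=True)
class Scenario:
    """Fully specified generative configuration for one experiment."""

    panel: MarkerPanel
    eta: float
    spec: MisclassSpec
    params: RiskParams  # true risk coefficients; beta0/kappa filled on creation
    design: StudyDesign
    missing_rate: float = 0.0
    model_kind: str = GEM

    @property
    def pi(self) -> float:
        return float(self.design.pi[0])

    def true_space(self) -> ParameterSpace:
        return ParameterSpace(self.panel.n_markers, model_kind=self.model_kind)

    def true_theta(self) -> pd.Series:
        space = self.true_space()
        vec = space.pack(self.params, ExposureModel(eta=self.eta), self.panel)
        return pd.Series(vec, index=space.names)


def make_scenario(
    panel: MarkerPanel,
    eta: float,
    spec: MisclassSpec,
    params: RiskParams,
    design: StudyDesign,
    missing_rate: float = 0.0,
) -> Scenario:
    """Complete a scenario: calibrate beta_0 to pi and derive kappa."""
    if design.pi is None:
        raise ValueError("scenario design must carry the target prevalence pi")
    b0 = calibrate_beta0(params, panel, eta, float(design.pi[0]))
    params = dc_replace(params, beta0=np.array([b0]))
    params = params.with_kappa_from_design(design)
    return Scenario(
        panel=panel,
        eta=eta,
        spec=spec,
        params=params,
        design=design,
        missing_rate=missing_rate,
        model_kind=params.model_kind,
    )


def simulate_case_control(
    scenario: Scenario,
    rng: np.random.Generator | int | None = None,
    method: str = "conditional",
) -> CaseControlData:
    """Draw one retrospective case-control sample under the scenario.

    ``method='conditional'`` samples (G, T) for each stratum from
    pr(G, T | D = d) exactly; ``method='rejection'`` draws iid population
    subjects until the case/control quotas are met (same distribution,
    kept as an oracle).  X is then drawn from the misclassification model
    and genotypes are masked MCAR at ``missing_rate``.
    """
    rng = np.random.default_rng(rng)
    sc = scenario
    n0, n1 = int(sc.design.n_d[0]), int(sc.design.n_d[1])
    states, t_grid, w, m = _population_grid(sc.panel, sc.eta, sc.params)
    p1 = expit(sc.params.beta0[0] + m)
    if method == "conditional":
        w_case = w * p1
        w_ctrl = w * (1.0 - p1)
        idx_ctrl = rng.choice(len(w), size=n0, p=w_ctrl / w_ctrl.sum())
        idx_case = rng.choice(len(w), size=n1, p=w_case / w_case.sum())
        idx = np.concatenate([idx_ctrl, idx_case])
        d = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    elif method == "rejection":
        got = {0: [], 1: []}
        while len(got[0]) < n0 or len(got[1]) < n1:
            batch = max(10000, 4 * int((n0 + n1) / max(sc.pi, 1e-6) / 50))
            cand = rng.choice(len(w), size=batch, p=w / w.sum())
            disease = rng.random(batch) < p1[cand]
            for dd in (0, 1):
                need = (n1 if dd else n0) - len(got[dd])
                if need > 0:
                    take = cand[disease == bool(dd)][:need]
                    got[dd].extend(take.tolist())
        idx = np.array(got[0] + got[1])
        d = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    else:
        raise ValueError("method must be 'conditional' or 'rejection'")
    g = states[idx % len(states)]
    t = t_grid[idx]
    # observed exposure through the misclassification process
    px1 = np.where(t == 1, 1.0 - sc.spec.xi0, sc.spec.xi1)
    x = (rng.random(idx.size) < px1).astype(int)
    g = g.copy()
    if sc.missing_rate > 0:
        mask = rng.random(g.shape) < sc.missing_rate
        g[mask] = MISSING
    perm = rng.permutation(idx.size)
    return CaseControlData(
        d=d[perm], x=x[perm], g=g[perm], design=StudyDesign([n0, n1], pi=[sc.pi])
    )


# ---------------------------------------------------------------------------
# shipped experiment designs
# ---------------------------------------------------------------------------

def _three_marker_panel(p: float = 0.25, delta: float = 0.03) -> MarkerPanel:
    d = np.full((3, 3), delta)
    np.fill_diagonal(d, 0.0)
    return MarkerPanel(np.full(3, p), d)


#: True risk coefficients of the large genotype-effect-model design.
TRUE_GEM = dict(
    beta_x=0.693,
    beta_a=(0.406, 0.789, 0.693),
    beta_ax=(0.916, 0.693, 1.099),
    beta_d=(0.262, 0.095, 0.693),
    beta_dx=(1.099, 0.916, 1.099),
)

#: True risk coefficients of the small additive-effect-model design.
TRUE_AEM_SMALL = dict(
    beta_x=1.099,
    beta_a=(0.406, 0.789, 0.693),
    beta_ax=(0.916, 0.693, 1.099),
)


def experiment1_scenario(
    n_cases: int = 1500,
    n_controls: int = 1500,
    missing_rate: float = 0.0,
    pi: float = 0.005,
) -> Scenario:
    """Large genotype-effect-model design (three markers, misclassified X)."""
    panel = _three_marker_panel()
    params = RiskParams(
        beta0=[0.0],
        beta_t=[TRUE_GEM["beta_x"]],
        beta_a=[TRUE_GEM["beta_a"]],
        beta_at=[TRUE_GEM["beta_ax"]],
        beta_d=[TRUE_GEM["beta_d"]],
        beta_dt=[TRUE_GEM["beta_dx"]],
        model_kind=GEM,
    )
    design = StudyDesign([n_controls, n_cases], pi=[pi])
    return make_scenario(
        panel, 0.5, MisclassSpec(xi0=0.20, xi1=0.25), params, design, missing_rate
    )


def small_sample_scenario(
    n_cases: int = 350, n_controls: int = 350, pi: float = 0.005
) -> Scenario:
    """Small additive-effect-model design (350/350, three markers)."""
    panel = _three_marker_panel()
    params = RiskParams(
        beta0=[0.0],
        beta_t=[TRUE_AEM_SMALL["beta_x"]],
        beta_a=[TRUE_AEM_SMALL["beta_a"]],
        beta_at=[TRUE_AEM_SMALL["beta_ax"]],
        model_kind=AEM,
    )
    design = StudyDesign([n_controls, n_cases], pi=[pi])
    return make_scenario(panel, 0.5, MisclassSpec(xi0=0.20, xi1=0.25), params, design)


def experiment2_scenario(**kwargs) -> Scenario:
    """Design for the asymptotic-posterior experiment (same as experiment 1)."""
    return experiment1_scenario(**kwargs)


# ---------------------------------------------------------------------------
# replicate runner
# ---------------------------------------------------------------------------

def run_experiment(
    scenario: Scenario,
    n_replicates: int,
    estimators: tuple[str, ...] = ("naive", "pseudo-mle"),
    seed: int | None = 0,
    mcmc_options: dict | None = None,
    parameters: list[str] | None = None,
) -> pd.DataFrame:
    """Bias/RMSE table over simulation replicates for the chosen estimators.

    Returns a long-format frame with columns (parameter, estimator, truth,
    bias, bias_mc_se, rmse, rmse_mc_se, sd, n_ok).  Replicate seeds are
    spawned deterministically from the master seed; estimator failures are
    recorded and excluded, never fatal.
    """
    from .asymptotic import asymptotic_posterior
    from .bayes import PriorSpec, run_mh
    from .pseudolik import fit_naive, fit_pseudo_mle

    allowed = {"naive", "pseudo-mle", "mcmc", "asymptotic"}
    if not set(estimators) <= allowed:
        raise ValueError(f"estimators must be a subset of {sorted(allowed)}")
    truth = scenario.true_theta()
    monitored = parameters or [n for n in truth.index]
    mcmc_options = dict(mcmc_options or {})
    seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    results: dict[str, list[pd.Series]] = {e: [] for e in estimators}
    failures: dict[str, int] = {e: 0 for e in estimators}
    for rep, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        data = simulate_case_control(scenario, rng=rng)
        mle = None
        for est in estimators:
            try:
                if est == "naive":
                    fit = fit_naive(data, model_kind=scenario.model_kind)
                    results[est].append(fit.estimates)
                    continue
                if mle is None:
                    mle = fit_pseudo_mle(
                        data,
                        scenario.spec,
                        model_kind=scenario.model_kind,
                        compute_vcov=(("mcmc" in estimators) or ("asymptotic" in estimators)),
                    )
                if est == "pseudo-mle":
                    results[est].append(mle.estimates)
                elif est == "mcmc":
                    chain = run_mh(
                        data,
                        PriorSpec.default(mle.space),
                        scenario.spec,
                        model_kind=scenario.model_kind,
                        seed=int(rng.integers(2**31 - 1)),
                        init=mle,
                        **mcmc_options,
                    )
                    results[est].append(chain.summaries["mean"])
                elif est == "asymptotic":
                    post = asymptotic_posterior(
                        data,
                        PriorSpec.default(mle.space),
                        scenario.spec,
                        model_kind=scenario.model_kind,
                        mle=mle,
                    )
                    results[est].append(
                        pd.Series(post.mean, index=mle.space.names)
                    )
            except Exception:
                failures[est] += 1
    rows = []
    for est in estimators:
        if not results[est]:
            continue
        mat = pd.DataFrame(results[est])
        for name in monitored:
            if name not in mat.columns or name not in truth.index:
                continue
            vals = mat[name].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                continue
            err = vals - truth[name]
            bias = err.mean()
            mse = float(np.mean(err**2))
            rmse = float(np.sqrt(mse))
            r = vals.size
            mse_se = float(np.std(err**2, ddof=1) / np.sqrt(r)) if r > 1 else np.nan
            rows.append(
                {
                    "parameter": name,
                    "estimator": est,
                    "truth": truth[name],
                    "bias": bias,
                    "bias_mc_se": err.std(ddof=1) / np.sqrt(r) if r > 1 else np.nan,
                    "rmse": rmse,
                    "rmse_mc_se": (
                        mse_se / (2 * rmse) if r > 1 and rmse > 0 else np.nan
                    ),
                    "mse": mse,
                    "mse_mc_se": mse_se,
                    "sd": vals.std(ddof=1) if r > 1 else np.nan,
                    "n_ok": r,
                    "n_failed": failures[est],
                }
            )
    return pd.DataFrame(rows)
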