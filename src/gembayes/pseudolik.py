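"""Retrospective pseudolikelihood for case-control gene-environment data.

Each subject contributes

    L_i = pr(D = d, G = g, X = x | Z = z, R = 1)
        = sum_{t*} S(d, g, t*, z) p_miss(x | t*) f_T(t* | z)
          / sum_{k*, t*, g*} S(k*, g*, t*, z) f_T(t* | z)

where S combines the logistic risk kernel, the retrospective offsets kappa
and the multilocus genotype distribution, the latent true exposure t* is
summed out against the misclassification model, and genotype vectors with
missing entries are additionally summed over their compatible completions.
Although the data are sampled retrospectively, maximizing this criterion
yields consistent, asymptotically normal estimates; conditioning on Z keeps
the criterion free of the covariate density f_Z.

Everything is evaluated in log space (log-sum-exp), with subjects collapsed
to their distinct (d, x, z, genotype-pattern) cells so that the cost of one
evaluation is driven by the 3^I genotype enumeration, not the sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit, logsumexp

from . import genotype as gt
from .errors import ExposureModel, MisclassSpec
from .genotype import MISSING, MarkerPanel
from .risk import AEM, GEM, RiskParams, StudyDesign

__all__ = [
    "CaseControlData",
    "FitResult",
    "ParameterSpace",
    "PseudoLikelihood",
    "log_pseudolik_obs",
    "fit_pseudo_mle",
    "fit_naive",
]

_PENALTY = -1e12


@dataclass
class CaseControlData:
    """Subject-level case-control data.

    Attributes
    ----------
    d : (n,) int array — disease category, 0 = control.
    x : (n,) int array — observed (error-prone) binary exposure.
    g : (n, I) int array — allele-M dosages 0/1/2, ``MISSING`` (-1) allowed.
    z : (n, nz) float array or None — exactly measured covariates.
    design : StudyDesign — case/control counts and optional prevalences.
    """

    d: np.ndarray
    x: np.ndarray
    g: np.ndarray
    z: np.ndarray | None = None
    design: StudyDesign | None = None
    marker_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=int)
        self.x = np.asarray(self.x, dtype=int)
        g = np.asarray(self.g, dtype=float)
        g = np.where(np.isnan(g), MISSING, g).astype(int)
        if g.ndim != 2:
            raise ValueError("g must be 2-D (subjects x markers)")
        if not np.all(np.isin(g, [MISSING, 0, 1, 2])):
            raise ValueError("genotype entries must be 0/1/2 or missing")
        if not np.all(np.isin(self.x, [0, 1])):
            raise ValueError("x must be binary")
        self.g = g
        if self.z is not None:
            self.z = np.atleast_2d(np.asarray(self.z, dtype=float))
            if self.z.shape[0] != self.d.size:
                self.z = self.z.T
        if self.design is None:
            k_max = int(self.d.max())
            counts = np.array([(self.d == k).sum() for k in range(k_max + 1)])
            self.design = StudyDesign(counts)
        else:
            counts = np.array(
                [(self.d == k).sum() for k in range(self.design.n_d.size)]
            )
            if not np.array_equal(counts, self.design.n_d.astype(int)):
                raise ValueError("observed category counts do not match design.n_d")

    @property
    def n(self) -> int:
        return int(self.d.size)

    @property
    def n_markers(self) -> int:
        return int(self.g.shape[1])

    @property
    def n_categories(self) -> int:
        return int(self.design.n_d.size - 1)

    def controls_genotypes(self) -> np.ndarray:
        return self.g[self.d == 0]


@dataclass
class FitResult:
    """Pseudo-MLE (or naive) fit: estimates, covariance and diagnostics."""

    estimates: pd.Series
    vcov: pd.DataFrame | None
    loglik: float
    converged: bool
    message: str = ""
    n_iter: int = 0
    grad_norm: float = np.nan
    params: RiskParams | None = None
    eta_model: ExposureModel | None = None
    panel: MarkerPanel | None = None
    space: "ParameterSpace | None" = None

    @property
    def se(self) -> pd.Series:
        if self.vcov is None:
            return pd.Series(np.nan, index=self.estimates.index)
        se = pd.Series(
            np.sqrt(np.clip(np.diag(self.vcov.to_numpy()), 0, None)),
            index=self.vcov.index,
        )
        return se.reindex(self.estimates.index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.estimates, "se": self.se})


class ParameterSpace:
    """Names, packing and transforms of the free parameter vector.

    The natural-scale vector stacks, for a binary disease (K = 1):
    ``kappa``, (``beta0`` when the prevalence is treated as unknown),
    ``beta_x``, covariate effects, additive blocks, dominance blocks (GEM),
    ``eta``, allele frequencies ``p_m`` and the pairwise LD coefficients
    ``delta``.  The unconstrained scale maps eta and p_m through logits and
    each delta through a scaled logit into its pairwise feasibility box.
    """

    def __init__(
        self,
        n_markers: int,
        model_kind: str = GEM,
        n_covariates: int = 0,
        pi_known: bool = True,
        estimate_theta: bool = True,
        estimate_eta: bool = True,
    ):
        if model_kind not in (GEM, AEM):
            raise ValueError("model_kind must be 'gem' or 'aem'")
        self.n_markers = n_markers
        self.model_kind = model_kind
        self.n_covariates = n_covariates
        self.pi_known = pi_known
        self.estimate_theta = estimate_theta
        self.estimate_eta = estimate_eta
        i = n_markers
        names: list[str] = ["kappa"]
        if not pi_known:
            names.append("beta0")
        names.append("beta_x")
        names += [f"beta_z{j+1}" for j in range(n_covariates)]
        names += [f"beta_a{j+1}" for j in range(i)]
        names += [f"beta_ax{j+1}" for j in range(i)]
        if n_covariates:
            names += [f"beta_az{j+1}" for j in range(i)]
        if model_kind == GEM:
            names += [f"beta_d{j+1}" for j in range(i)]
            names += [f"beta_dx{j+1}" for j in range(i)]
            if n_covariates:
                names += [f"beta_dz{j+1}" for j in range(i)]
        self._risk_slice = slice(0, len(names))
        if estimate_eta:
            names.append("eta")
            names += [f"eta_z{j+1}" for j in range(n_covariates)]
        if estimate_theta:
            names += [f"p_m{j+1}" for j in range(i)]
            self._pairs = [(a, b) for a in range(i) for b in range(a + 1, i)]
            names += [f"delta{a+1}{b+1}" for a, b in self._pairs]
        else:
            self._pairs = [(a, b) for a in range(i) for b in range(a + 1, i)]
        self.names = names
        self.index = {n: j for j, n in enumerate(names)}
        # vectorized-transform caches
        self._logit_idx = np.array(
            [self.index[n] for n in names if n == "eta" or n.startswith("p_m")],
            dtype=int,
        )
        if estimate_theta and self._pairs:
            self._delta_idx = np.array(
                [self.index[f"delta{a+1}{b+1}"] for a, b in self._pairs], dtype=int
            )
            self._delta_p_idx = np.array(
                [[self.index[f"p_m{a+1}"], self.index[f"p_m{b+1}"]] for a, b in self._pairs],
                dtype=int,
            )
        else:
            self._delta_idx = np.array([], dtype=int)
            self._delta_p_idx = np.zeros((0, 2), dtype=int)

    @property
    def n_params(self) -> int:
        return len(self.names)

    def risk_coefficient_names(self) -> list[str]:
        """Names of the regression coefficients that take the normal prior."""
        skip = {"kappa", "beta0", "eta", "p_m", "delta"}
        return [
            n
            for n in self.names
            if not (n in ("kappa", "beta0", "eta") or n.startswith(("p_m", "delta", "eta_z")))
        ]

    def _take(self, theta: np.ndarray, prefix: str, count: int) -> np.ndarray:
        return np.array([theta[self.index[f"{prefix}{j+1}"]] for j in range(count)])

    def unpack(
        self,
        theta: np.ndarray,
        design: StudyDesign,
        fixed_eta: ExposureModel | None = None,
        fixed_panel: MarkerPanel | None = None,
        validate_panel: bool = True,
    ) -> tuple[RiskParams, ExposureModel, MarkerPanel]:
        """Natural-scale vector -> (RiskParams, ExposureModel, MarkerPanel)."""
        theta = np.asarray(theta, dtype=float)
        i, nz = self.n_markers, self.n_covariates
        kappa = theta[self.index["kappa"]]
        if self.pi_known:
            beta0 = kappa - design.log_offset()[0]
        else:
            beta0 = theta[self.index["beta0"]]
        kwargs = dict(
            beta0=np.array([beta0]),
            kappa=np.array([kappa]),
            beta_t=theta[self.index["beta_x"]],
            beta_a=self._take(theta, "beta_a", i)[None, :],
            beta_at=self._take(theta, "beta_ax", i)[None, :],
            model_kind=self.model_kind,
        )
        if nz:
            kwargs["beta_z"] = self._take(theta, "beta_z", nz)[None, :]
            kwargs["beta_az"] = self._take(theta, "beta_az", i)[None, :]
        if self.model_kind == GEM:
            kwargs["beta_d"] = self._take(theta, "beta_d", i)[None, :]
            kwargs["beta_dt"] = self._take(theta, "beta_dx", i)[None, :]
            if nz:
                kwargs["beta_dz"] = self._take(theta, "beta_dz", i)[None, :]
        params = RiskParams(**kwargs)
        if self.estimate_eta:
            eta = float(theta[self.index["eta"]])
            eta_z = self._take(theta, "eta_z", nz) if nz else None
            eta_model = ExposureModel(eta=eta, eta_z=eta_z)
        else:
            eta_model = fixed_eta
        if self.estimate_theta:
            p = self._take(theta, "p_m", i)
            delta = np.zeros((i, i))
            for (a, b) in self._pairs:
                v = theta[self.index[f"delta{a+1}{b+1}"]]
                delta[a, b] = delta[b, a] = v
            if validate_panel:
                panel = MarkerPanel(p, delta)
            else:
                panel = object.__new__(MarkerPanel)
                object.__setattr__(panel, "p_m", p)
                object.__setattr__(panel, "delta", delta)
        else:
            panel = fixed_panel
        return params, eta_model, panel

    def pack(
        self,
        params: RiskParams,
        eta_model: ExposureModel | None,
        panel: MarkerPanel | None,
    ) -> np.ndarray:
        theta = np.zeros(self.n_params)
        i, nz = self.n_markers, self.n_covariates
        theta[self.index["kappa"]] = params.kappa[0]
        if not self.pi_known:
            theta[self.index["beta0"]] = params.beta0[0]
        theta[self.index["beta_x"]] = params.beta_t[0]
        for j in range(i):
            theta[self.index[f"beta_a{j+1}"]] = params.beta_a[0, j]
            theta[self.index[f"beta_ax{j+1}"]] = params.beta_at[0, j]
        if nz:
            for j in range(nz):
                theta[self.index[f"beta_z{j+1}"]] = params.beta_z[0, j]
            for j in range(i):
                theta[self.index[f"beta_az{j+1}"]] = params.beta_az[0, j]
        if self.model_kind == GEM:
            for j in range(i):
                theta[self.index[f"beta_d{j+1}"]] = params.beta_d[0, j]
                theta[self.index[f"beta_dx{j+1}"]] = params.beta_dt[0, j]
            if nz:
                for j in range(i):
                    theta[self.index[f"beta_dz{j+1}"]] = params.beta_dz[0, j]
        if self.estimate_eta:
            theta[self.index["eta"]] = eta_model.eta
            if nz:
                for j in range(nz):
                    theta[self.index[f"eta_z{j+1}"]] = eta_model.eta_z[j]
        if self.estimate_theta:
            for j in range(i):
                theta[self.index[f"p_m{j+1}"]] = panel.p_m[j]
            for (a, b) in self._pairs:
                theta[self.index[f"delta{a+1}{b+1}"]] = panel.delta[a, b]
        return theta

    # --- unconstrained <-> natural ------------------------------------
    def _delta_box(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pa = theta[self._delta_p_idx[:, 0]]
        pb = theta[self._delta_p_idx[:, 1]]
        qa, qb = 1.0 - pa, 1.0 - pb
        return np.maximum(-pa * pb, -qa * qb), np.minimum(pa * qb, qa * pb)

    def to_unconstrained(self, theta: np.ndarray) -> np.ndarray:
        u = np.array(theta, dtype=float, copy=True)
        u[self._logit_idx] = logit(np.clip(theta[self._logit_idx], 1e-9, 1 - 1e-9))
        if self._delta_idx.size:
            lo, hi = self._delta_box(np.asarray(theta, dtype=float))
            frac = np.clip((theta[self._delta_idx] - lo) / (hi - lo), 1e-9, 1 - 1e-9)
            u[self._delta_idx] = logit(frac)
        return u

    def to_natural(self, u: np.ndarray) -> np.ndarray:
        theta = np.array(u, dtype=float, copy=True)
        theta[self._logit_idx] = expit(theta[self._logit_idx])
        if self._delta_idx.size:
            lo, hi = self._delta_box(theta)
            theta[self._delta_idx] = lo + (hi - lo) * expit(u[self._delta_idx])
        return theta

    def log_jacobian(self, u: np.ndarray) -> float:
        """log |d natural / d unconstrained| for the MH Jacobian correction."""
        u = np.asarray(u, dtype=float)
        v = expit(u[self._logit_idx])
        lj = float(np.sum(np.log(v) + np.log1p(-v)))
        if self._delta_idx.size:
            theta = self.to_natural(u)
            lo, hi = self._delta_box(theta)
            w = expit(u[self._delta_idx])
            lj += float(np.sum(np.log(hi - lo) + np.log(w) + np.log1p(-w)))
        return lj


class PseudoLikelihood:
    """Vectorized evaluator of the retrospective log pseudolikelihood.

    Subjects are collapsed to distinct (d, x, z-row, genotype-pattern) cells;
    one evaluation enumerates the 3^I genotype set per distinct covariate row
    and reuses it across subjects.
    """

    def __init__(
        self,
        data: CaseControlData,
        spec: MisclassSpec,
        model_kind: str = GEM,
        enum_cap: int = gt.DEFAULT_ENUM_CAP,
    ):
        self.data = data
        self.spec = spec
        self.model_kind = model_kind
        self.n_categories = data.n_categories
        self.states = gt.genotype_states(data.n_markers, cap=enum_cap)  # (Ng, I)
        self.codes_a = self.states.astype(float) - 1.0
        i = data.n_markers
        # distinct covariate rows
        if data.z is None or data.z.shape[1] == 0:
            self._z_rows = np.zeros((1, 0))
            z_idx = np.zeros(data.n, dtype=int)
        else:
            self._z_rows, z_idx = np.unique(data.z, axis=0, return_inverse=True)
        # distinct observation patterns
        key = np.column_stack([data.d, data.x, z_idx, data.g])
        self._cells, inverse, counts = np.unique(
            key, axis=0, return_inverse=True, return_counts=True
        )
        self._cell_of_subject = inverse
        self._counts = counts.astype(float)
        # genotype-compatibility matrix per cell (handles missing entries)
        gpat = self._cells[:, 3:]
        obs = gpat[:, None, :] != MISSING  # (C, 1, I)
        self._compat = np.all(
            (gpat[:, None, :] == self.states[None, :, :]) | ~obs, axis=2
        ).astype(float)  # (C, Ng)
        self._cell_d = self._cells[:, 0]
        self._cell_x = self._cells[:, 1]
        self._cell_z = self._cells[:, 2]
        self._pmiss = spec.matrix()  # P[x, t]
        # fast-path caches (binary disease, no covariates)
        self._fast_ready = (
            self.n_categories == 1 and self._z_rows.shape[1] == 0
        )
        if self._fast_ready:
            pats = gt.haplotype_patterns(i)
            self._hap_patterns = pats
            self._hap_signs = np.where(pats == 1, 1.0, -1.0)
            w3 = 3 ** np.arange(i - 1, -1, -1)
            self._hap_sum_idx = (pats[:, None, :] + pats[None, :, :]) @ w3
            self._pairs_ij = [(a, b) for a in range(i) for b in range(a + 1, i)]
            self._pair_rest = []
            for (a, b) in self._pairs_ij:
                others = [k for k in range(i) if k not in (a, b)]
                self._pair_rest.append(np.array(others, dtype=int))
            with np.errstate(divide="ignore"):
                self._log_pmiss = np.log(self._pmiss)

    def _fast_space_cache(self, space: "ParameterSpace"):
        cache = getattr(self, "_space_cache", None)
        if cache is not None and cache[0] is space:
            return cache[1]
        i = self.data.n_markers
        ix = space.index
        blocks = {
            "kappa": ix["kappa"],
            "beta0": ix.get("beta0") if not space.pi_known else None,
            "beta_x": ix["beta_x"],
            "beta_a": np.array([ix[f"beta_a{j+1}"] for j in range(i)]),
            "beta_ax": np.array([ix[f"beta_ax{j+1}"] for j in range(i)]),
            "eta": ix["eta"],
            "p_m": np.array([ix[f"p_m{j+1}"] for j in range(i)]),
            "delta": np.array(
                [ix[f"delta{a+1}{b+1}"] for (a, b) in self._pairs_ij]
            )
            if self._pairs_ij
            else np.array([], dtype=int),
            "gem": space.model_kind == GEM,
        }
        if blocks["gem"]:
            blocks["beta_d"] = np.array([ix[f"beta_d{j+1}"] for j in range(i)])
            blocks["beta_dx"] = np.array([ix[f"beta_dx{j+1}"] for j in range(i)])
        blocks["offset"] = (
            self.data.design.log_offset()[0] if space.pi_known else None
        )
        self._space_cache = (space, blocks)
        return blocks

    def _fast_cell_loglik(self, theta: np.ndarray, space: "ParameterSpace"):
        """Vectorized cell log-pseudolikelihood for the binary no-covariate case.

        Algebraically identical to :meth:`cell_loglik`; returns None for
        out-of-support parameter values.
        """
        bl = self._fast_space_cache(space)
        p = theta[bl["p_m"]]
        eta = theta[bl["eta"]]
        if np.any(p <= 0) or np.any(p >= 1) or not (0.0 < eta < 1.0):
            return None
        # haplotype and genotype probabilities
        pats = self._hap_patterns
        marg = np.where(pats == 1, p, 1.0 - p)
        h = marg.prod(axis=1)
        for k, (a, b) in enumerate(self._pairs_ij):
            rest = self._pair_rest[k]
            prod_rest = marg[:, rest].prod(axis=1) if rest.size else 1.0
            h = h + theta[bl["delta"][k]] * self._hap_signs[:, a] * self._hap_signs[:, b] * prod_rest
        if np.any(h < -1e-12):
            return None
        h = np.clip(h, 0.0, None)
        pg = np.bincount(
            self._hap_sum_idx.ravel(),
            weights=np.outer(h, h).ravel(),
            minlength=len(self.states),
        )
        with np.errstate(divide="ignore"):
            log_pg = np.log(pg)
        # linear predictors over genotype states
        kappa = theta[bl["kappa"]]
        beta0 = kappa - bl["offset"] if bl["offset"] is not None else theta[bl["beta0"]]
        a_codes = self.codes_a
        m_lin = a_codes @ theta[bl["beta_a"]]
        m_int = theta[bl["beta_x"]] + a_codes @ theta[bl["beta_ax"]]
        if bl["gem"]:
            q = 1.0 - p
            b_codes = np.stack([-(p**2), p * q, -(q**2)])[self.states, np.arange(p.size)]
            m_lin = m_lin + b_codes @ theta[bl["beta_d"]]
            m_int = m_int + b_codes @ theta[bl["beta_dx"]]
        log_ft = np.log([1.0 - eta, eta])
        log_s = np.empty((2, 2, len(a_codes)))  # (k, t, state)
        for t in (0, 1):
            m = m_lin + t * m_int
            log_denom = np.logaddexp(0.0, beta0 + m)
            log_s[0, t] = -log_denom + log_pg
            log_s[1, t] = kappa + m - log_denom + log_pg
        # all log-sum-exps below use an explicit max shift (scipy-free hot path)
        shifted = log_s + log_ft[None, :, None]
        mx_den = shifted.max()
        log_den = np.log(np.exp(shifted - mx_den).sum()) + mx_den
        mx = log_s.max()
        es = np.exp(log_s - mx)  # (2, 2, Ng)
        inner = np.empty((self.n_cells, 2))
        rows = np.arange(self.n_cells)
        for t in (0, 1):
            plane = self._compat @ es[:, t, :].T  # (C, 2) over k
            with np.errstate(divide="ignore"):
                inner[:, t] = np.log(plane[rows, self._cell_d]) + mx
        terms = inner + self._log_pmiss[self._cell_x] + log_ft[None, :]
        log_num = np.logaddexp(terms[:, 0], terms[:, 1])
        return log_num - log_den

    @property
    def n_cells(self) -> int:
        return len(self._cells)

    def _log_s(self, params: RiskParams, panel: MarkerPanel, z_row: np.ndarray):
        """log S over (k = 0..K, t = 0/1, genotype states) for one z row."""
        a = self.codes_a
        b = (
            gt._dominance_table(panel.p_m)[self.states, np.arange(panel.n_markers)]
            if params.model_kind == GEM
            else None
        )
        try:
            _, pg = gt.joint_genotype_distribution(panel)
        except gt.InvalidLDError:
            return None
        with np.errstate(divide="ignore"):
            log_pg = np.log(pg)
        z = z_row[None, :].repeat(len(a), axis=0) if z_row.size else None
        from .risk import linear_predictor

        out = np.empty((self.n_categories + 1, 2, len(a)))
        for t in (0, 1):
            m = linear_predictor(a, b, np.full(len(a), float(t)), z, params)  # (Ng, K)
            logits = params.beta0 + m
            log_denom = logsumexp(
                np.concatenate([np.zeros((len(a), 1)), logits], axis=1), axis=1
            )
            out[0, t] = -log_denom + log_pg
            for k in range(1, self.n_categories + 1):
                out[k, t] = params.kappa[k - 1] + m[:, k - 1] - log_denom + log_pg
        return out

    def cell_loglik(
        self,
        params: RiskParams,
        eta_model: ExposureModel,
        panel: MarkerPanel,
    ) -> np.ndarray | None:
        """Log pseudolikelihood of each distinct observation cell."""
        if params.kappa is None:
            raise ValueError("RiskParams.kappa is required")
        out = np.empty(self.n_cells)
        for zi in range(len(self._z_rows)):
            z_row = self._z_rows[zi]
            log_s = self._log_s(params, panel, z_row)
            if log_s is None:
                return None
            pt1 = float(eta_model.prob(z_row if z_row.size else None))
            if not (0.0 < pt1 < 1.0):
                return None
            log_ft = np.log([1.0 - pt1, pt1])
            # denominator: sum over k, t, g
            log_den = logsumexp(log_s + log_ft[None, :, None])
            sel = self._cell_z == zi
            compat = self._compat[sel]  # (c, Ng)
            d_sel = self._cell_d[sel]
            x_sel = self._cell_x[sel]
            # inner_g[c, t] = logsumexp over compatible g of log_s[d_c, t, :]
            s_d = log_s[d_sel]  # (c, 2, Ng)
            mx = s_d.max(axis=2, keepdims=True)
            inner = np.log(
                np.einsum("cg,ctg->ct", compat, np.exp(s_d - mx))
            ) + mx[:, :, 0]
            with np.errstate(divide="ignore"):
                log_pm = np.log(self._pmiss[x_sel])  # (c, 2) over t
            log_num = logsumexp(inner + log_pm + log_ft[None, :], axis=1)
            out[sel] = log_num - log_den
        return out

    def loglik(
        self, params: RiskParams, eta_model: ExposureModel, panel: MarkerPanel
    ) -> float:
        cells = self.cell_loglik(params, eta_model, panel)
        if cells is None or not np.all(np.isfinite(cells)):
            return _PENALTY
        return float(self._counts @ cells)

    def per_subject(
        self, params: RiskParams, eta_model: ExposureModel, panel: MarkerPanel
    ) -> np.ndarray:
        cells = self.cell_loglik(params, eta_model, panel)
        if cells is None:
            raise ValueError("parameters imply an infeasible genotype distribution")
        return cells[self._cell_of_subject]

    # --- flat-vector interfaces used by optimizers/samplers ------------
    def loglik_natural(
        self, theta: np.ndarray, space: ParameterSpace, method: str = "auto"
    ) -> float:
        theta = np.asarray(theta, dtype=float)
        if self._fast_ready and method == "auto":
            cells = self._fast_cell_loglik(theta, space)
            if cells is None or not np.all(np.isfinite(cells)):
                return _PENALTY
            return float(self._counts @ cells)
        try:
            params, eta_model, panel = space.unpack(
                theta, self.data.design, validate_panel=False
            )
        except (ValueError, gt.InvalidLDError):
            return _PENALTY
        return self.loglik(params, eta_model, panel)

    def loglik_unconstrained(self, u: np.ndarray, space: ParameterSpace) -> float:
        return self.loglik_natural(space.to_natural(u), space)

    def per_subject_natural(
        self, theta: np.ndarray, space: ParameterSpace, method: str = "auto"
    ) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        if self._fast_ready and method == "auto":
            cells = self._fast_cell_loglik(theta, space)
            if cells is not None:
                return cells[self._cell_of_subject]
        params, eta_model, panel = space.unpack(
            theta, self.data.design, validate_panel=False
        )
        return self.per_subject(params, eta_model, panel)


def log_pseudolik_obs(
    d: int,
    g,
    x: int,
    z,
    params: RiskParams,
    eta_model: ExposureModel,
    spec: MisclassSpec,
    panel: MarkerPanel,
) -> float:
    """Log pseudolikelihood contribution of a single observation.

    Convenience scalar interface; ``g`` may contain ``MISSING`` entries, in
    which case the numerator marginalizes over compatible completions.
    """
    g = np.atleast_1d(np.asarray(g))
    design = StudyDesign(np.ones(params.n_categories + 1))
    data = CaseControlData(
        d=np.array([d] + [k for k in range(params.n_categories + 1) if k != d]),
        x=np.array([x] * (params.n_categories + 1)),
        g=np.vstack([g] * (params.n_categories + 1)),
        z=None if z is None else np.vstack([np.atleast_1d(z)] * (params.n_categories + 1)),
    )
    pl = PseudoLikelihood(data, spec, model_kind=params.model_kind)
    return float(pl.per_subject(params, eta_model, panel)[0])


# ---------------------------------------------------------------------------
# numerical derivatives (central differences on the given scale)
# ---------------------------------------------------------------------------

def _gradient(f, x: np.ndarray, step: float = 1e-5) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    for j in range(x.size):
        h = step * max(1.0, abs(x[j]))
        e = np.zeros_like(x)
        e[j] = h
        g[j] = (f(x + e) - f(x - e)) / (2 * h)
    return g


def _jacobian(f, x: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Jacobian of a vector-valued f, columns are parameter directions."""
    x = np.asarray(x, dtype=float)
    cols = []
    for j in range(x.size):
        h = step * max(1.0, abs(x[j]))
        e = np.zeros_like(x)
        e[j] = h
        cols.append((f(x + e) - f(x - e)) / (2 * h))
    return np.column_stack(cols)


def _hessian(f, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    return _jacobian(lambda y: _gradient(f, y, step=step), x, step=step)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _initial_theta(
    data: CaseControlData,
    spec: MisclassSpec,
    space: ParameterSpace,
) -> np.ndarray:
    """Moment-style starting values: naive logistic fit + corrected exposure
    prevalence + control-sample genotype parameters."""
    panel0 = gt.estimate_panel(data.controls_genotypes())
    denom = 1.0 - spec.xi0 - spec.xi1
    eta0 = float(np.clip((data.x.mean() - spec.xi1) / denom, 0.05, 0.95))
    naive = fit_naive(data, model_kind=space.model_kind, panel=panel0)
    theta = np.zeros(space.n_params)
    for name in space.names:
        j = space.index[name]
        if name in naive.estimates.index:
            v = naive.estimates[name]
            theta[j] = v if np.isfinite(v) else 0.0
        elif name == "eta":
            theta[j] = eta0
        elif name == "beta0":
            theta[j] = naive.estimates.get("kappa", 0.0)
        elif name.startswith("p_m"):
            theta[j] = panel0.p_m[int(name[3:]) - 1]
        elif name.startswith("delta"):
            a, b = int(name[5]) - 1, int(name[6]) - 1
            theta[j] = panel0.delta[a, b]
    # keep coefficients in a sane range for the first iterations
    for name in space.names:
        if name.startswith("beta") or name == "kappa":
            j = space.index[name]
            theta[j] = float(np.clip(theta[j], -3.0, 3.0))
    return theta


def sandwich_vcov(
    pl: PseudoLikelihood,
    theta_hat: np.ndarray,
    space: ParameterSpace,
    return_pieces: bool = False,
):
    """Sandwich covariance H^{-1} V H^{-1} with the case-control correction.

    H is minus the Hessian of the total log pseudolikelihood; V is the
    variance of the total score, estimated within disease strata:
    ``V = sum_d n_d Cov_d(Psi)`` (equivalently ``n (Sigma_raw - Lambda)``
    with Lambda built from stratum-mean scores).
    """
    d = pl.data.d
    n = pl.data.n
    psi = _jacobian(lambda th: pl.per_subject_natural(th, space), theta_hat)  # (n, p)
    hess = _hessian(lambda th: pl.loglik_natural(th, space), theta_hat)
    h = -(hess + hess.T) / 2.0
    v = np.zeros((space.n_params, space.n_params))
    lam = np.zeros_like(v)
    for k in np.unique(d):
        rows = psi[d == k]
        mu = rows.mean(axis=0)
        centered = rows - mu
        v += centered.T @ centered
        lam += (rows.shape[0] / n) * np.outer(mu, mu)
    h_inv = _robust_inv(h)
    vcov = h_inv @ v @ h_inv
    vcov = (vcov + vcov.T) / 2.0
    if return_pieces:
        sigma_hat = (psi - psi.mean(axis=0)).T @ (psi - psi.mean(axis=0)) / n
        return vcov, {"H": h, "V": v, "Lambda": lam, "Sigma": sigma_hat, "scores": psi}
    return vcov


def _robust_inv(m: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(m)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(m)


def fit_pseudo_mle(
    data: CaseControlData,
    spec: MisclassSpec,
    model_kind: str = GEM,
    pi_known: bool = True,
    gtol: float = 1e-8,
    maxiter: int = 1000,
    compute_vcov: bool = True,
    theta0: np.ndarray | None = None,
    enum_cap: int = gt.DEFAULT_ENUM_CAP,
) -> FitResult:
    """Maximize the retrospective pseudolikelihood (quasi-Newton, log space).

    Optimization runs on an unconstrained reparameterization (logits for eta
    and allele frequencies, a scaled logit into the pairwise feasibility box
    for each LD coefficient); the reported estimates, covariance and scores
    are on the natural scale.  The sandwich covariance applies the
    case-control (stratum-mean) correction to the score variance.
    """
    from scipy.optimize import minimize

    if data.n_categories != 1:
        raise NotImplementedError("fitting is implemented for binary disease (K = 1)")
    nz = 0 if data.z is None else data.z.shape[1]
    if pi_known and (data.design.pi is None):
        pi_known = False
    space = ParameterSpace(
        data.n_markers, model_kind=model_kind, n_covariates=nz, pi_known=pi_known
    )
    pl = PseudoLikelihood(data, spec, model_kind=model_kind, enum_cap=enum_cap)
    theta_init = _initial_theta(data, spec, space) if theta0 is None else np.asarray(theta0, float)
    u0 = space.to_unconstrained(theta_init)

    def nll(u):
        return -pl.loglik_unconstrained(u, space)

    res = minimize(nll, u0, method="BFGS", options={"gtol": gtol, "maxiter": maxiter})
    if not res.success and np.linalg.norm(res.jac) > 0.5:
        # genuine non-convergence (not just precision loss): one restart
        res2 = minimize(
            nll, res.x, method="BFGS", options={"gtol": gtol, "maxiter": maxiter}
        )
        if res2.fun <= res.fun:
            res = res2
    theta_hat = space.to_natural(res.x)
    grad = _gradient(lambda th: pl.loglik_natural(th, space), theta_hat)
    converged = bool(res.success) or float(np.linalg.norm(res.jac)) < 0.05
    vcov_df = None
    if compute_vcov:
        vcov = sandwich_vcov(pl, theta_hat, space)
        vcov_df = pd.DataFrame(vcov, index=space.names, columns=space.names)
    params, eta_model, panel = space.unpack(theta_hat, data.design)
    est = pd.Series(theta_hat, index=space.names)
    boundary = (
        not (0.01 < eta_model.eta < 0.99)
        or np.any(panel.p_m < 0.01)
        or np.any(panel.p_m > 0.99)
    )
    message = res.message + (" [boundary estimate]" if boundary else "")
    return FitResult(
        estimates=est,
        vcov=vcov_df,
        loglik=float(-res.fun),
        converged=converged,
        message=message,
        n_iter=int(res.nit),
        grad_norm=float(np.max(np.abs(grad))),
        params=params,
        eta_model=eta_model,
        panel=panel,
        space=space,
    )


def fit_naive(
    data: CaseControlData,
    model_kind: str = GEM,
    panel: MarkerPanel | None = None,
) -> FitResult:
    """Prospective logistic regression ignoring misclassification.

    Regresses D on the observed exposure X, the genotype codes and their
    interactions, treating X as if it were the true exposure.  The dominance
    code uses allele frequencies counted in the controls.  The reported
    ``kappa`` is the logistic intercept (which estimates the retrospective
    offset under case-control sampling); ``p_m`` are the control-sample
    allele frequencies.
    """
    import statsmodels.api as sm

    if data.n_categories != 1:
        raise NotImplementedError("naive fit requires binary disease")
    complete = ~np.any(data.g == MISSING, axis=1)
    d = data.d[complete]
    x = data.x[complete].astype(float)
    g = data.g[complete]
    if panel is None:
        panel = gt.estimate_panel(data.controls_genotypes())
    a = g.astype(float) - 1.0
    i = data.n_markers
    cols = {"kappa": np.ones(d.size), "beta_x": x}
    nz = 0 if data.z is None else data.z.shape[1]
    if nz:
        zc = data.z[complete]
        for j in range(nz):
            cols[f"beta_z{j+1}"] = zc[:, j]
    for j in range(i):
        cols[f"beta_a{j+1}"] = a[:, j]
    for j in range(i):
        cols[f"beta_ax{j+1}"] = x * a[:, j]
    if nz:
        for j in range(i):
            cols[f"beta_az{j+1}"] = data.z[complete][:, 0] * a[:, j]
    if model_kind == GEM:
        b = gt.encode_dominance(g, panel)
        for j in range(i):
            cols[f"beta_d{j+1}"] = b[:, j]
        for j in range(i):
            cols[f"beta_dx{j+1}"] = x * b[:, j]
        if nz:
            for j in range(i):
                cols[f"beta_dz{j+1}"] = data.z[complete][:, 0] * b[:, j]
    design_mat = pd.DataFrame(cols)
    converged, message = True, ""
    try:
        fit = sm.Logit(d, design_mat).fit(disp=0, maxiter=200)
        est = fit.params.copy()
        vcov = fit.cov_params()
        converged = bool(fit.mle_retvals.get("converged", True))
        loglik = float(fit.llf)
    except Exception as exc:  # separation and similar failures
        est = pd.Series(np.nan, index=design_mat.columns)
        vcov = pd.DataFrame(np.nan, index=design_mat.columns, columns=design_mat.columns)
        converged, message, loglik = False, f"naive fit failed: {exc}", np.nan
    for j in range(i):
        est[f"p_m{j+1}"] = panel.p_m[j]
    return FitResult(
        estimates=est,
        vcov=vcov,
        loglik=loglik,
        converged=converged,
        message=message or "naive prospective logistic fit",
        panel=panel,
    )
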