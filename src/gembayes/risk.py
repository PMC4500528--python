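"""Penetrance and retrospective-sampling kernels.

Disease risk follows a polytomous logistic model

    pr(D = k >= 1 | G, T, Z) = exp{beta_k0 + m_k} / (1 + sum_j exp{beta_j0 + m_j})

whose linear predictor ``m_k`` carries the exposure T, exact covariates Z and
the genotype through additive codes A and (under the genotype effect model)
dominance codes B, together with their multiplicative interactions.  The
additive effect model (AEM) is the genotype effect model (GEM) with every
dominance block removed.

Retrospective case-control sampling enters through the intercept offsets

    kappa_k = beta_k0 + log(n_k / n_0) - log(pi_k / pi_0)

which absorb the sampling fractions and the population prevalences pi_k, and
through the S kernel combining the risk term with the genotype distribution.
All kernels are evaluated in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

from .genotype import MarkerPanel, encode_additive, encode_dominance, genotype_states, joint_genotype_distribution

__all__ = [
    "GEM",
    "AEM",
    "RiskParams",
    "StudyDesign",
    "linear_predictor",
    "disease_probability",
    "s_kernel",
]

GEM = "gem"
AEM = "aem"


def _as2d(x, k: int, width: int | None = None) -> np.ndarray:
    """Coerce a coefficient block to shape (K, width)."""
    if x is None:
        return np.zeros((k, 0 if width is None else width))
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.ndim == 1:
        arr = arr[None, :] if (width is None or arr.size == width) else arr[:, None]
    return arr


@dataclass(frozen=True)
class RiskParams:
    """Coefficients of the polytomous logistic risk model (K disease categories).

    Coefficient blocks are stored with a leading category axis of length K;
    scalars/1-D input is accepted for the binary-disease case K=1.  Under the
    additive effect model the dominance blocks must be structurally zero.
    """

    beta0: np.ndarray  # (K,) intercepts
    kappa: np.ndarray | None = None  # (K,) retrospective offsets
    beta_t: np.ndarray = 0.0  # (K,) exposure main effect
    beta_z: np.ndarray | None = None  # (K, nz)
    beta_a: np.ndarray | None = None  # (K, I) additive main effects
    beta_at: np.ndarray | None = None  # (K, I) additive x exposure
    beta_az: np.ndarray | None = None  # (K, I) additive x scalar Z
    beta_d: np.ndarray | None = None  # (K, I) dominance main effects
    beta_dt: np.ndarray | None = None  # (K, I) dominance x exposure
    beta_dz: np.ndarray | None = None  # (K, I) dominance x scalar Z
    model_kind: str = GEM

    def __post_init__(self) -> None:
        b0 = np.atleast_1d(np.asarray(self.beta0, dtype=float))
        k = b0.size
        object.__setattr__(self, "beta0", b0)
        if self.kappa is not None:
            kap = np.atleast_1d(np.asarray(self.kappa, dtype=float))
            if kap.size != k:
                raise ValueError("kappa must have length K")
            object.__setattr__(self, "kappa", kap)
        object.__setattr__(self, "beta_t", np.atleast_1d(np.asarray(self.beta_t, dtype=float)))
        if self.beta_t.size != k:
            raise ValueError("beta_t must have length K")
        i = None
        for name in ("beta_a", "beta_at", "beta_az", "beta_d", "beta_dt", "beta_dz"):
            block = getattr(self, name)
            if block is not None:
                arr = _as2d(block, k)
                if arr.shape[0] != k:
                    raise ValueError(f"{name} must have leading dimension K={k}")
                i = arr.shape[1] if i is None else i
                if arr.shape[1] != i:
                    raise ValueError("genotype coefficient blocks disagree on the number of markers")
                object.__setattr__(self, name, arr)
        if self.beta_z is not None:
            object.__setattr__(self, "beta_z", _as2d(self.beta_z, k))
        if self.model_kind not in (GEM, AEM):
            raise ValueError("model_kind must be 'gem' or 'aem'")
        if self.model_kind == AEM:
            for name in ("beta_d", "beta_dt", "beta_dz"):
                block = getattr(self, name)
                if block is not None and np.any(np.asarray(block) != 0.0):
                    raise ValueError(f"additive effect model forbids nonzero {name}")

    @property
    def n_categories(self) -> int:
        return int(self.beta0.size)

    @property
    def n_markers(self) -> int:
        for name in ("beta_a", "beta_at", "beta_az", "beta_d", "beta_dt", "beta_dz"):
            block = getattr(self, name)
            if block is not None:
                return block.shape[1]
        return 0

    def with_kappa_from_design(self, design: "StudyDesign") -> "RiskParams":
        return replace(self, kappa=self.beta0 + design.log_offset())

    def with_beta0_from_kappa(self, design: "StudyDesign") -> "RiskParams":
        if self.kappa is None:
            raise ValueError("kappa is not set")
        return replace(self, beta0=self.kappa - design.log_offset())


@dataclass(frozen=True)
class StudyDesign:
    """Case-control design counts and (optional) population prevalences.

    ``n_d[0]`` is the number of controls and ``n_d[k]`` the number of cases in
    category k; ``pi[k-1]`` is the population prevalence of category k.
    """

    n_d: np.ndarray
    pi: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = np.atleast_1d(np.asarray(self.n_d, dtype=float))
        if np.any(n < 1):
            raise ValueError("all design counts must be >= 1")
        object.__setattr__(self, "n_d", n)
        if self.pi is not None:
            p = np.atleast_1d(np.asarray(self.pi, dtype=float))
            if p.size != n.size - 1:
                raise ValueError("pi must have one entry per case category")
            if np.any(p <= 0) or p.sum() >= 1.0:
                raise ValueError("prevalences must be positive and sum to < 1")
            object.__setattr__(self, "pi", p)

    @property
    def n_categories(self) -> int:
        return int(self.n_d.size - 1)

    @property
    def n_total(self) -> int:
        return int(self.n_d.sum())

    def log_offset(self) -> np.ndarray:
        """log(n_k/n_0) - log(pi_k/pi_0) for k = 1..K (needs prevalences)."""
        if self.pi is None:
            raise ValueError("prevalences pi are required for the kappa/beta0 identity")
        pi0 = 1.0 - self.pi.sum()
        return np.log(self.n_d[1:] / self.n_d[0]) - np.log(self.pi / pi0)


def linear_predictor(a, b, t, z, params: RiskParams, k: int | None = None) -> np.ndarray:
    """Linear predictor(s) m_k(A, B, T, Z; beta).

    Parameters
    ----------
    a, b : arrays of shape (..., I)
        Additive and dominance codes; ``b`` is ignored under the AEM and may
        be None.
    t : scalar or array
        Exposure value(s).
    z : array of shape (..., nz) or None
    k : int or None
        Disease category in 1..K; None returns all K predictors stacked on
        the last axis.
    """
    a = np.asarray(a, dtype=float)
    t = np.asarray(t, dtype=float)
    kk = params.n_categories
    i = params.n_markers
    if i and a.shape[-1] != i:
        raise ValueError(f"expected {i} markers, got {a.shape[-1]}")

    def block(name):
        blk = getattr(params, name)
        return np.zeros((kk, i)) if blk is None else blk

    m = t[..., None] * params.beta_t  # (..., K)
    if i:
        m = m + a @ block("beta_a").T
        m = m + t[..., None] * (a @ block("beta_at").T)
    if z is not None and params.beta_z is not None and params.beta_z.shape[1]:
        z = np.asarray(z, dtype=float)
        m = m + z @ params.beta_z.T
        if i and params.beta_az is not None:
            m = m + z[..., :1] * (a @ block("beta_az").T)
    if params.model_kind == GEM and b is not None and i:
        b = np.asarray(b, dtype=float)
        m = m + b @ block("beta_d").T
        m = m + t[..., None] * (b @ block("beta_dt").T)
        if z is not None and params.beta_dz is not None:
            m = m + np.asarray(z)[..., :1] * (b @ block("beta_dz").T)
    if k is not None:
        if not (1 <= k <= kk):
            raise ValueError("k must be in 1..K")
        return m[..., k - 1]
    return m


def disease_probability(a, b, t, z, params: RiskParams) -> np.ndarray:
    """Probability vector over disease categories k = 0..K (log-space safe)."""
    m = linear_predictor(a, b, t, z, params)  # (..., K)
    logits = params.beta0 + m
    log_denom = logsumexp(np.concatenate([np.zeros(logits.shape[:-1] + (1,)), logits], axis=-1), axis=-1)
    pk = np.exp(logits - log_denom[..., None])
    p0 = np.exp(-log_denom)
    return np.concatenate([p0[..., None], pk], axis=-1)


def s_kernel(
    k: int,
    g,
    t,
    z,
    params: RiskParams,
    panel: MarkerPanel,
    log: bool = True,
):
    """log S(k, g, t, z): retrospective risk kernel times genotype probability.

    ``S = exp[1(k>=1){kappa_k + m_k}] / (1 + sum_j exp{beta_j0 + m_j}) * pr(g)``
    with a numerator of 1 for controls (k = 0).
    """
    if k >= 1 and params.kappa is None:
        raise ValueError("kappa offsets are required for case categories (k >= 1)")
    g = np.asarray(g)
    a = encode_additive(g)
    b = encode_dominance(g, panel) if params.model_kind == GEM else None
    m = linear_predictor(a, b, np.asarray(t, dtype=float), z, params)  # (..., K)
    logits = params.beta0 + m
    log_denom = logsumexp(
        np.concatenate([np.zeros(logits.shape[:-1] + (1,)), logits], axis=-1), axis=-1
    )
    states, probs = joint_genotype_distribution(panel)
    weights = 3 ** np.arange(panel.n_markers - 1, -1, -1)
    log_pg = np.log(probs[np.asarray(g) @ weights])
    num = 0.0 if k == 0 else params.kappa[k - 1] + m[..., k - 1]
    out = num - log_denom + log_pg
    return out if log else np.exp(out)
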