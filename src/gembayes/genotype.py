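"""Multilocus genotype model: allele-frequency/LD parameterization under HWE.

A marker panel is parameterized by per-marker allele-M frequencies ``P_M`` and
a symmetric matrix of pairwise composite linkage-disequilibrium coefficients
``Delta`` (the covariance between the allele indicators of two markers on the
same haplotype).  Haplotype frequencies are built from these first two moments
with all third- and higher-order disequilibria set to zero; genotypes are two
independent haplotype draws (Hardy-Weinberg equilibrium at the haplotype
level).

The additive code ``A = g - 1`` and the zero-mean dominance code ``B`` derived
from the allele frequencies have closed-form moments under this construction:

    E(A_i) = P_Mi - P_mi          Var(A_i) = 2 P_Mi P_mi
    E(B_i) = 0                    Var(B_i) = P_Mi^2 P_mi^2
    Cov(A_i, A_j) = 2 Delta_ij    Cov(B_i, B_j) = Delta_ij^2
    Cov(A_i, B_j) = 0

which the module exposes as the block covariance matrices ``V_A`` and ``V_D``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MISSING",
    "MarkerPanel",
    "InvalidLDError",
    "MissingGenotypeError",
    "EnumerationCapError",
    "encode_additive",
    "encode_dominance",
    "haplotype_frequencies",
    "joint_genotype_distribution",
    "coding_moments",
    "estimate_panel",
]

#: Sentinel for a missing genotype call (callers marginalize over completions).
MISSING: int = -1

#: Default cap on the number of markers enumerable jointly (3**10 genotypes).
DEFAULT_ENUM_CAP: int = 10


class InvalidLDError(ValueError):
    """A pairwise-Delta configuration implies a negative haplotype frequency."""


class MissingGenotypeError(ValueError):
    """A coding operation received a genotype vector with missing entries."""


class EnumerationCapError(ValueError):
    """Joint enumeration requested for more markers than the configured cap."""


def _delta_bounds(p_i: float, p_j: float) -> tuple[float, float]:
    """Feasibility box for the pairwise LD coefficient of two markers."""
    q_i, q_j = 1.0 - p_i, 1.0 - p_j
    lo = max(-p_i * p_j, -q_i * q_j)
    hi = min(p_i * q_j, q_i * p_j)
    return lo, hi


@dataclass(frozen=True)
class MarkerPanel:
    """Allele frequencies and pairwise LD defining the genotype distribution.

    Parameters
    ----------
    p_m : array-like of shape (I,)
        Frequency of allele M at each marker, each strictly inside (0, 1).
    delta : array-like of shape (I, I), optional
        Symmetric matrix of pairwise LD coefficients; the diagonal is unused.
        Defaults to linkage equilibrium (all zeros).
    """

    p_m: np.ndarray
    delta: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        p = np.atleast_1d(np.asarray(self.p_m, dtype=float))
        if p.ndim != 1 or p.size == 0:
            raise ValueError("p_m must be a non-empty 1-D array")
        if np.any((p <= 0.0) | (p >= 1.0)):
            raise ValueError("allele frequencies must lie strictly in (0, 1)")
        d = self.delta
        if d is None:
            d = np.zeros((p.size, p.size))
        d = np.asarray(d, dtype=float)
        if d.shape != (p.size, p.size):
            raise ValueError(f"delta must have shape {(p.size, p.size)}")
        if not np.allclose(d, d.T):
            raise ValueError("delta must be symmetric")
        for i, j in itertools.combinations(range(p.size), 2):
            lo, hi = _delta_bounds(p[i], p[j])
            if not (lo <= d[i, j] <= hi):
                raise InvalidLDError(
                    f"delta[{i},{j}]={d[i, j]:g} outside pairwise bounds "
                    f"[{lo:g}, {hi:g}] for P_M=({p[i]:g}, {p[j]:g})"
                )
        object.__setattr__(self, "p_m", p)
        object.__setattr__(self, "delta", d)
        # implied haplotype table must be a probability distribution
        haplotype_frequencies(self)

    @property
    def n_markers(self) -> int:
        return int(self.p_m.size)

    def with_delta_zero(self) -> "MarkerPanel":
        """The same panel under linkage equilibrium."""
        return MarkerPanel(self.p_m.copy(), np.zeros_like(self.delta))


def pairwise_delta(panel: MarkerPanel) -> np.ndarray:
    """Upper-triangle pairwise LD coefficients, row-major order."""
    i, j = np.triu_indices(panel.n_markers, k=1)
    return panel.delta[i, j]


def encode_additive(g: np.ndarray) -> np.ndarray:
    """Additive (allele-dosage) code ``A_i = g_i - 1`` in {-1, 0, +1}.

    ``A_i = 1`` for the M_iM_i homozygote, 0 for the heterozygote and -1 for
    the m_im_i homozygote.  Missing entries are rejected: callers holding
    incomplete genotypes must marginalize over completions instead.
    """
    g = np.asarray(g)
    if np.any(g == MISSING) or (np.issubdtype(g.dtype, np.floating) and np.any(np.isnan(g))):
        raise MissingGenotypeError("cannot encode a genotype vector with missing entries")
    if np.any((g < 0) | (g > 2)):
        raise ValueError("genotype entries must be 0, 1 or 2")
    return np.asarray(g, dtype=float) - 1.0


def encode_dominance(g: np.ndarray, panel: MarkerPanel) -> np.ndarray:
    """Zero-mean dominance code B_i.

    B_i equals ``-P_mi^2`` for M_iM_i, ``P_Mi P_mi`` for M_im_i and
    ``-P_Mi^2`` for m_im_i, so that E(B_i) = 0 under per-marker HWE.
    """
    a = encode_additive(g)  # validates entries / missingness
    p = panel.p_m
    if a.shape[-1] != panel.n_markers:
        raise ValueError("genotype length does not match the panel")
    q = 1.0 - p
    table = np.stack([-(p**2), p * q, -(q**2)], axis=0)  # rows: g=0,1,2
    gi = (a + 1.0).astype(int)
    return table[gi, np.arange(p.size)]  # broadcasts over leading axes of g


def _dominance_table(p: np.ndarray) -> np.ndarray:
    """(3, I) table of B codes indexed by genotype value 0/1/2."""
    q = 1.0 - p
    return np.stack([-(p**2), p * q, -(q**2)], axis=0)


def haplotype_patterns(n_markers: int) -> np.ndarray:
    """All 2**I allele patterns (1 = allele M), shape (2**I, I)."""
    return np.array(list(itertools.product((0, 1), repeat=n_markers)), dtype=int)


def haplotype_frequencies(panel: MarkerPanel) -> tuple[np.ndarray, np.ndarray]:
    """Haplotype table implied by (P_M, Delta) with zero higher-order LD.

    For allele pattern ``a`` the frequency is

        h(a) = prod_k p_k(a_k)
               + sum_{i<j} Delta_ij s_i s_j prod_{k != i,j} p_k(a_k)

    with ``p_k(1) = P_Mk``, ``p_k(0) = P_mk`` and sign ``s_k = +1`` if the
    pattern carries M at marker k, else -1.  Margins equal P_M and the
    covariance of allele indicators equals Delta exactly.

    Returns
    -------
    patterns : (2**I, I) int array of allele patterns (1 = M).
    freqs : (2**I,) float array of haplotype probabilities.

    Raises
    ------
    InvalidLDError
        If any implied frequency is negative; the message names the pattern.
    """
    p = panel.p_m
    n = p.size
    patterns = haplotype_patterns(n)
    marg = np.where(patterns == 1, p, 1.0 - p)  # (H, I)
    freqs = marg.prod(axis=1)
    signs = np.where(patterns == 1, 1.0, -1.0)
    for i, j in itertools.combinations(range(n), 2):
        others = [k for k in range(n) if k not in (i, j)]
        rest = marg[:, others].prod(axis=1) if others else np.ones(len(patterns))
        freqs = freqs + panel.delta[i, j] * signs[:, i] * signs[:, j] * rest
    tol = 1e-12
    if np.any(freqs < -tol):
        k = int(np.argmin(freqs))
        alleles = "".join("M" if a else "m" for a in patterns[k])
        raise InvalidLDError(
            f"implied haplotype frequency for pattern {alleles} is negative "
            f"({freqs[k]:.3g}); the pairwise Delta configuration is infeasible"
        )
    freqs = np.clip(freqs, 0.0, None)
    return patterns, freqs


def genotype_states(n_markers: int, cap: int = DEFAULT_ENUM_CAP) -> np.ndarray:
    """All 3**I genotype vectors, shape (3**I, I)."""
    if n_markers > cap:
        raise EnumerationCapError(
            f"joint enumeration over {n_markers} markers exceeds the cap of "
            f"{cap} (3**{n_markers} genotype vectors); raise the cap explicitly "
            "if this is intentional"
        )
    return np.array(list(itertools.product((0, 1, 2), repeat=n_markers)), dtype=int)


def joint_genotype_distribution(
    panel: MarkerPanel, cap: int = DEFAULT_ENUM_CAP
) -> tuple[np.ndarray, np.ndarray]:
    """Probability of every multilocus genotype under haplotype-level HWE.

    A genotype is the elementwise sum of two independent haplotype draws:
    ``pr(g) = sum_{a + b = g} h(a) h(b)``.

    Returns
    -------
    states : (3**I, I) int array of genotype vectors.
    probs : (3**I,) float array summing to 1.
    """
    states = genotype_states(panel.n_markers, cap=cap)
    patterns, h = haplotype_frequencies(panel)
    n = panel.n_markers
    # genotype a+b indexed in the base-3 enumeration used by genotype_states
    weights = 3 ** np.arange(n - 1, -1, -1)
    probs = np.zeros(3**n)
    sums = (patterns[:, None, :] + patterns[None, :, :]) @ weights  # (H, H)
    np.add.at(probs, sums.ravel(), np.outer(h, h).ravel())
    return states, probs


def coding_moments(panel: MarkerPanel) -> dict[str, np.ndarray]:
    """Closed-form moments of the additive/dominance codes.

    Returns a dict with entries ``E_A``, ``E_B``, ``V_A``, ``V_D`` where
    ``V_A[i, j] = 2 Delta_ij`` off-diagonal with ``2 P_Mi P_mi`` on the
    diagonal, and ``V_D[i, j] = Delta_ij^2`` with ``P_Mi^2 P_mi^2`` on the
    diagonal.  ``Cov(A, B) = 0``, so the joint covariance of the stacked
    codes is block-diagonal ``[[V_A, 0], [0, V_D]]``.
    """
    p = panel.p_m
    q = 1.0 - p
    v_a = 2.0 * panel.delta.copy()
    np.fill_diagonal(v_a, 2.0 * p * q)
    v_d = panel.delta.copy() ** 2
    np.fill_diagonal(v_d, (p * q) ** 2)
    return {
        "E_A": p - q,
        "E_B": np.zeros_like(p),
        "V_A": v_a,
        "V_D": v_d,
    }


def sample_genotypes(
    panel: MarkerPanel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` multilocus genotypes as sums of two iid haplotypes."""
    patterns, h = haplotype_frequencies(panel)
    probs = h / h.sum()
    a = rng.choice(len(patterns), size=n, p=probs)
    b = rng.choice(len(patterns), size=n, p=probs)
    return patterns[a] + patterns[b]


def estimate_panel(genotypes: np.ndarray, missing_ok: bool = True) -> MarkerPanel:
    """Estimate (P_M, Delta) from a genotype matrix by allele counting.

    ``P_M`` is the allele-count MLE per marker; ``Delta`` is the composite
    genotypic covariance of allele counts between markers divided by 2,
    using pairwise-complete observations.  Typically applied to controls,
    which approximate the source population when the disease is rare.
    """
    g = np.asarray(genotypes, dtype=float)
    g = np.where(g == MISSING, np.nan, g)
    if not missing_ok and np.any(np.isnan(g)):
        raise MissingGenotypeError("missing genotypes not allowed here")
    p = np.nanmean(g, axis=0) / 2.0
    p = np.clip(p, 1e-6, 1.0 - 1e-6)
    n_markers = g.shape[1]
    delta = np.zeros((n_markers, n_markers))
    for i, j in itertools.combinations(range(n_markers), 2):
        ok = ~np.isnan(g[:, i]) & ~np.isnan(g[:, j])
        if ok.sum() >= 2:
            cov = np.cov(g[ok, i], g[ok, j])[0, 1] / 2.0
            lo, hi = _delta_bounds(p[i], p[j])
            eps = 1e-9
            delta[i, j] = delta[j, i] = np.clip(cov, lo + eps, hi - eps)
    try:
        return MarkerPanel(p, delta)
    except InvalidLDError:
        # pairwise-feasible but jointly infeasible: shrink toward equilibrium
        for lam in np.linspace(0.9, 0.0, 10):
            try:
                return MarkerPanel(p, lam * delta)
            except InvalidLDError:
                continue
        return MarkerPanel(p, np.zeros_like(delta))
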