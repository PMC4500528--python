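"""Exposure misclassification model and exposure prevalence model.

The observed binary exposure X is an error-prone surrogate for the true
exposure T.  Nondifferential misclassification is parameterized by the
false-negative probability ``xi0 = pr(X=0 | T=1)`` and the false-positive
probability ``xi1 = pr(X=1 | T=0)``; identifiability requires xi0 + xi1 < 1.
A pluggable hook admits differential models p(x | t, g, z, d).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["MisclassSpec", "ExposureModel", "p_miss", "GeneralMisclassification"]


@dataclass(frozen=True)
class MisclassSpec:
    """Nondifferential misclassification probabilities of the binary exposure.

    Attributes
    ----------
    xi0 : float
        pr(X = 0 | T = 1), the false-negative probability.
    xi1 : float
        pr(X = 1 | T = 0), the false-positive probability.
    """

    xi0: float = 0.0
    xi1: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.xi0 < 1.0 and 0.0 <= self.xi1 < 1.0):
            raise ValueError("xi0 and xi1 must lie in [0, 1)")
        if self.xi0 + self.xi1 >= 1.0:
            raise ValueError(
                "xi0 + xi1 must be < 1 for the exposure model to be identifiable"
            )

    def matrix(self) -> np.ndarray:
        """(2, 2) array P[x, t] = pr(X=x | T=t)."""
        return np.array(
            [[1.0 - self.xi1, self.xi0], [self.xi1, 1.0 - self.xi0]]
        )


@dataclass(frozen=True)
class ExposureModel:
    """Prevalence model for the true exposure, pr(T = 1) = eta.

    When exactly measured covariates Z are present the prevalence follows a
    logistic link pr(T=1 | z) = expit(eta0 + z . eta_z).
    """

    eta: float = 0.5
    eta_z: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.eta_z is None:
            if not (0.0 < self.eta < 1.0):
                raise ValueError("eta must lie strictly in (0, 1)")

    def prob(self, z: np.ndarray | None = None) -> np.ndarray:
        """pr(T = 1) (or pr(T=1 | z) rowwise when Z-dependent)."""
        if self.eta_z is None or z is None:
            return np.asarray(self.eta)
        from scipy.special import expit

        lin = np.log(self.eta / (1 - self.eta)) + np.asarray(z) @ np.asarray(self.eta_z)
        return expit(lin)


def p_miss(x, t, spec: MisclassSpec):
    """pr(X = x | T = t) under nondifferential misclassification.

    Evaluates ``{x xi1 + (1-x)(1-xi1)}(1-t) + {x(1-xi0) + (1-x) xi0} t``;
    for each fixed t the probabilities over x sum to one.
    """
    x = np.asarray(x)
    t = np.asarray(t)
    if np.any((x != 0) & (x != 1)) or np.any((t != 0) & (t != 1)):
        raise ValueError("x and t must be 0/1")
    return (x * spec.xi1 + (1 - x) * (1.0 - spec.xi1)) * (1 - t) + (
        x * (1.0 - spec.xi0) + (1 - x) * spec.xi0
    ) * t


class GeneralMisclassification:
    """Registry for a user-supplied differential model p(x | t, g, z, d).

    The default reproduces the nondifferential :func:`p_miss`.  A registered
    model is validated to be a proper conditional distribution (sums to one
    over x) on the full conditioning grid supplied at registration.
    """

    def __init__(self, spec: MisclassSpec):
        self.spec = spec
        self._model: Callable | None = None

    def register(
        self,
        model: Callable[..., float],
        grid: dict[str, list] | None = None,
        atol: float = 1e-10,
    ) -> None:
        """Register ``model(x, t, g, z, d)``; audit normalization over x.

        ``grid`` maps the names ``t``, ``g``, ``z``, ``d`` to the lists of
        values over which normalization is checked (defaults to t, d binary
        with g and z absent).
        """
        grid = grid or {}
        ts = grid.get("t", [0, 1])
        gs = grid.get("g", [None])
        zs = grid.get("z", [None])
        ds = grid.get("d", [0, 1])
        for t, g, z, d in itertools.product(ts, gs, zs, ds):
            total = sum(model(x, t, g, z, d) for x in (0, 1))
            if abs(total - 1.0) > atol:
                raise ValueError(
                    f"registered misclassification model is unnormalized at "
                    f"(t={t}, g={g}, z={z}, d={d}): sum over x = {total:g}"
                )
        self._model = model

    def __call__(self, x, t, g=None, z=None, d=None):
        if self._model is None:
            return p_miss(x, t, self.spec)
        return self._model(x, t, g, z, d)
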