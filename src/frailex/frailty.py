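"""Frailty distributions and marginalized (observed-scale) quantities.

An individual frailty ``lam`` is a positive random multiplier on the excess
hazard, constrained to unit mean so that its variance ``b`` indexes the
amount of unobserved heterogeneity.  Marginalizing the conditional survival
``exp(-lam * HE)`` over the frailty distribution G gives the marginal net
survival as the Laplace transform of G evaluated at HE:

    S~N(t; x) = L_G{HE(t; x)}.

For the gamma frailty everything is closed form:

    L_G{s}       = (1 + b s)^(-1/b)
    S~N(t; x)    = 1 / (1 + b HE)^(1/b)
    h~(t; x)     = hP + hE / (1 + b HE)

with the time-dependent weight ``omega = 1 / (1 + b HE)`` equal to the mean
frailty among survivors, E[lam | T >= t] — the selection-of-the-healthier
effect.  A unit-mean inverse-Gaussian frailty (variance b) is also provided:
L_G{s} = exp{(1 - sqrt(1 + 2 b s)) / b}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FrailtySpec", "marginal_observed_survival", "marginal_observed_hazard"]

FAMILIES = ("none", "gamma", "inverse_gaussian")

# below this variance the closed forms are numerically indistinguishable from
# the no-frailty exp(-s) limit and we switch to it explicitly
_B_TINY = 1e-8


@dataclass(frozen=True)
class FrailtySpec:
    """A unit-mean frailty distribution.

    Parameters
    ----------
    family : str
        ``"none"`` (degenerate at 1), ``"gamma"``, or ``"inverse_gaussian"``.
    b : float
        Variance of the frailty (nonnegative).  Ignored when
        ``family="none"``.
    """

    family: str = "gamma"
    b: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown frailty family {self.family!r}; choose from {FAMILIES}")
        if not np.isfinite(self.b) or self.b < 0:
            raise ValueError(f"b must be a nonnegative finite real, got {self.b!r}")

    @property
    def effective_b(self) -> float:
        return 0.0 if self.family == "none" else float(self.b)

    def laplace(self, s):
        """Laplace transform L_G(s) of the frailty distribution, s >= 0."""
        arr = np.asarray(s, dtype=float)
        if np.any(arr < 0):
            raise ValueError("s must be nonnegative")
        b = self.effective_b
        if b < _B_TINY:
            out = np.exp(-arr)
        elif self.family == "gamma":
            out = np.exp(-np.log1p(b * arr) / b)
        else:  # inverse_gaussian
            out = np.exp((1.0 - np.sqrt(1.0 + 2.0 * b * arr)) / b)
        return float(out) if np.isscalar(s) else out

    def marginal_net_survival(self, HE):
        """Marginal net survival L_G{HE}; exp(-HE) when there is no frailty."""
        return self.laplace(HE)

    def frailty_weight(self, HE):
        """Time-dependent weight omega = -L'_G{HE} / L_G{HE} = E[lam | T >= t].

        Equals ``1 / (1 + b HE)`` for the gamma frailty and
        ``1 / sqrt(1 + 2 b HE)`` for the inverse Gaussian; 1.0 when there is
        no frailty (or b = 0).
        """
        arr = np.asarray(HE, dtype=float)
        if np.any(arr < 0):
            raise ValueError("HE must be nonnegative")
        b = self.effective_b
        if b < _B_TINY:
            out = np.ones_like(arr)
        elif self.family == "gamma":
            out = 1.0 / (1.0 + b * arr)
        else:
            out = 1.0 / np.sqrt(1.0 + 2.0 * b * arr)
        return float(out) if np.isscalar(HE) else out

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n frailties (unit mean, variance b)."""
        b = self.effective_b
        if b < _B_TINY:
            return np.ones(n)
        if self.family == "gamma":
            return rng.gamma(shape=1.0 / b, scale=b, size=n)
        return rng.wald(1.0, 1.0 / b, size=n)  # IG(mu=1, shape=1/b): var = b

    def to_dict(self) -> dict:
        return {"family": self.family, "b": float(self.b)}

    @classmethod
    def from_dict(cls, d: dict) -> "FrailtySpec":
        return cls(family=d.get("family", "gamma"), b=float(d.get("b", 0.0)))


def marginal_observed_survival(frailty, gh, lifetable, t, x, age, year, strata=None):
    """Marginal observed (all-cause) survival for one individual.

    The product of the conditional population survival ratio
    ``exp{-[HP(age+t) - HP(age)]}`` and the frailty-marginal net survival
    ``L_G{HE(t; x)}``.
    """
    t_arr = np.asarray(t, dtype=float)
    HP = lifetable.cum_hazard_increment(age, year, t_arr, strata)
    HE = gh.excess_cum_hazard(t_arr, x)
    out = np.exp(-np.asarray(HP)) * frailty.marginal_net_survival(HE)
    return float(out) if np.isscalar(t) else out


def marginal_observed_hazard(frailty, gh, lifetable, t, x, age, year, strata=None):
    """Marginal observed hazard: hP(age+t; year+t) + omega(t) * hE(t; x)."""
    t_arr = np.asarray(t, dtype=float)
    hP = lifetable.pop_hazard(np.asarray(age) + t_arr, np.asarray(year) + t_arr, strata)
    hE = gh.excess_hazard(t_arr, x)
    HE = gh.excess_cum_hazard(t_arr, x)
    out = np.asarray(hP) + frailty.frailty_weight(HE) * hE
    return float(out) if np.isscalar(t) else out
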