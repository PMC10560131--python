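"""Parametric baseline hazard families.

The default baseline is the power generalized Weibull (PGW) distribution,
a three-parameter lifetime distribution whose hazard can be increasing,
decreasing, unimodal, or bathtub-shaped while keeping the hazard, survival,
and quantile functions in closed form.  With scale ``sigma > 0`` and shapes
``nu, gamma > 0`` the survival function used throughout this package is

    S0(t) = exp{ 1 - [1 + (t/sigma)^nu]^(1/gamma) },

so the cumulative hazard is ``H0(t) = [1 + (t/sigma)^nu]^(1/gamma) - 1`` and
the quantile function inverts it in closed form.  Two simpler two-parameter
families (log-normal and log-logistic, each parametrized by a scale ``sigma``
and a shape ``nu``) are provided for model comparison.

All evaluations are done in log space where overflow is a concern (large
shape values such as ``gamma = 8`` produce huge powers otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr, ndtri

__all__ = [
    "FAMILIES",
    "BaselineParams",
    "hazard",
    "log_hazard",
    "cum_hazard",
    "inv_cum_hazard",
    "inv_cdf",
]

FAMILIES = ("pgw", "lognormal", "loglogistic")
_TWO_PARAM = frozenset({"lognormal", "loglogistic"})


@dataclass(frozen=True)
class BaselineParams:
    """Parameters of a baseline hazard family.

    Parameters
    ----------
    family : str
        One of ``"pgw"``, ``"lognormal"``, ``"loglogistic"``.
    sigma : float
        Scale parameter, in time units (years); must be positive.
    nu : float
        Shape parameter; must be positive.
    gamma : float, optional
        Second shape parameter, used only by the PGW family; must be
        positive.  Ignored (and not serialized) for two-parameter families.
    """

    family: str
    sigma: float
    nu: float
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown baseline family {self.family!r}; choose from {FAMILIES}")
        for name in ("sigma", "nu", "gamma"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be a positive finite real, got {value!r}")

    @property
    def n_params(self) -> int:
        """Number of free parameters (2 or 3)."""
        return 2 if self.family in _TWO_PARAM else 3

    def to_dict(self) -> dict:
        d = {"family": self.family, "sigma": float(self.sigma), "nu": float(self.nu)}
        if self.n_params == 3:
            d["gamma"] = float(self.gamma)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BaselineParams":
        return cls(
            family=d["family"],
            sigma=float(d["sigma"]),
            nu=float(d["nu"]),
            gamma=float(d.get("gamma", 1.0)),
        )


def _as_time(t, name: str = "t"):
    arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    if np.any(arr < 0):
        raise ValueError(f"{name} must be nonnegative")
    return arr, np.isscalar(t) or arr.ndim == 0


def _maybe_scalar(arr, scalar: bool):
    return float(arr) if scalar else arr


def log_hazard(p: BaselineParams, t) -> np.ndarray | float:
    """Log baseline hazard ``log h0(t)``.

    At ``t = 0`` the analytic limit is used: ``-inf`` (hazard 0) when
    ``nu > 1``, a finite value when ``nu == 1``, and a :class:`ValueError`
    when ``nu < 1`` (the hazard diverges at the origin).
    """
    arr, scalar = _as_time(t)
    zero = arr == 0
    if np.any(zero) and p.nu < 1:
        raise ValueError(f"hazard diverges at t=0 for nu={p.nu} < 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        logts = np.log(arr) - np.log(p.sigma)
        if p.family == "pgw":
            y = p.nu * logts
            out = (
                np.log(p.nu)
                - np.log(p.gamma)
                - np.log(p.sigma)
                + (p.nu - 1.0) * logts
                + (1.0 / p.gamma - 1.0) * np.logaddexp(0.0, y)
            )
            limit0 = -np.inf if p.nu > 1 else -np.log(p.sigma * p.gamma)
        elif p.family == "lognormal":
            z = logts / p.nu
            # log pdf of lognormal minus log survival
            logpdf = -np.log(arr) - np.log(p.nu) - 0.5 * np.log(2 * np.pi) - 0.5 * z**2
            out = logpdf - log_ndtr(-z)
            limit0 = -np.inf
        else:  # loglogistic
            y = p.nu * logts
            out = np.log(p.nu) - np.log(p.sigma) + (p.nu - 1.0) * logts - np.logaddexp(0.0, y)
            limit0 = -np.inf if p.nu > 1 else -np.log(p.sigma)
        out = np.where(zero, limit0, out)
    return _maybe_scalar(out, scalar)


def hazard(p: BaselineParams, t) -> np.ndarray | float:
    """Baseline hazard ``h0(t)`` (deaths per year)."""
    lh = log_hazard(p, t)
    return np.exp(lh)


def cum_hazard(p: BaselineParams, t) -> np.ndarray | float:
    """Baseline cumulative hazard ``H0(t) = -log S0(t)``; ``H0(0) = 0``."""
    arr, scalar = _as_time(t)
    with np.errstate(divide="ignore"):
        logts = np.log(arr) - np.log(p.sigma)
        if p.family == "pgw":
            y = p.nu * logts
            out = np.expm1(np.logaddexp(0.0, y) / p.gamma)
        elif p.family == "lognormal":
            z = logts / p.nu
            out = -log_ndtr(-z)
            out = np.where(arr == 0, 0.0, out)
        else:  # loglogistic
            y = p.nu * logts
            out = np.logaddexp(0.0, y)
            out = np.where(arr == 0, 0.0, out)
    return _maybe_scalar(out, scalar)


def inv_cum_hazard(p: BaselineParams, v) -> np.ndarray | float:
    """Inverse of the cumulative hazard: smallest t with ``H0(t) = v``."""
    arr = np.asarray(v, dtype=float)
    scalar = np.isscalar(v) or arr.ndim == 0
    if np.any(arr < 0):
        raise ValueError("cumulative hazard values must be nonnegative")
    with np.errstate(divide="ignore", over="ignore"):
        if p.family == "pgw":
            out = p.sigma * np.expm1(p.gamma * np.log1p(arr)) ** (1.0 / p.nu)
        elif p.family == "lognormal":
            u = -np.expm1(-arr)  # 1 - exp(-v)
            out = np.where(arr == 0, 0.0, np.exp(np.log(p.sigma) + p.nu * ndtri(u)))
        else:  # loglogistic
            out = p.sigma * np.expm1(arr) ** (1.0 / p.nu)
        out = np.where(np.isinf(arr), np.inf, out)
    return _maybe_scalar(out, scalar)


def inv_cdf(p: BaselineParams, u) -> np.ndarray | float:
    """Quantile function ``F0^{-1}(u)`` for ``u`` in ``[0, 1)``."""
    arr = np.asarray(u, dtype=float)
    scalar = np.isscalar(u) or arr.ndim == 0
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr >= 1):
        raise ValueError("u must lie in [0, 1)")
    out = inv_cum_hazard(p, -np.log1p(-arr))
    return _maybe_scalar(np.asarray(out), scalar)


def cdf(p: BaselineParams, t) -> np.ndarray | float:
    """Distribution function ``F0(t) = 1 - exp(-H0(t))``."""
    H = cum_hazard(p, t)
    return -np.expm1(-np.asarray(H)) if not np.isscalar(H) else -np.expm1(-H)
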