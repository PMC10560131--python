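"""General hazard (GH) structure for the excess hazard.

The excess hazard of an individual with covariates ``x`` (a subset ``w`` of
which acts on the time scale) is modelled as

    hE(t; x) = h0(t * exp(w'alpha)) * exp(x'beta),

with cumulative hazard ``HE(t; x) = H0(t * exp(w'alpha)) * exp(x'beta - w'alpha)``.
This structure nests proportional hazards (alpha = 0), accelerated hazards
(beta = 0), and accelerated failure time (w = x, alpha = beta) models, and
admits exact inverse-transform simulation of event times, with or without a
multiplicative frailty on the hazard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import baseline as bl
from .baseline import BaselineParams

__all__ = ["GHModel"]


@dataclass(frozen=True)
class GHModel:
    """A general-hazard excess hazard model with fixed parameters.

    Parameters
    ----------
    baseline : BaselineParams
        Baseline hazard family and parameters (theta).
    alpha : array-like
        Time-level effects, one per selected time covariate.
    beta : array-like
        Hazard-level effects, one per covariate column.
    time_index : tuple of int
        Indices of the covariate columns that form ``w`` (so ``w`` is a
        subset of ``x``).  Must have the same length as ``alpha``.
    """

    baseline: BaselineParams
    alpha: tuple = ()
    beta: tuple = ()
    time_index: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", tuple(float(a) for a in np.atleast_1d(self.alpha)) if np.size(self.alpha) else ())
        object.__setattr__(self, "beta", tuple(float(b) for b in np.atleast_1d(self.beta)) if np.size(self.beta) else ())
        object.__setattr__(self, "time_index", tuple(int(i) for i in self.time_index))
        if len(self.time_index) != len(self.alpha):
            raise ValueError(
                f"alpha has length {len(self.alpha)} but {len(self.time_index)} "
                "time covariates are selected"
            )
        if any(i < 0 or i >= len(self.beta) for i in self.time_index):
            raise ValueError("time_index entries must index into the covariate vector")

    # -- constructor helpers for the nested structures ------------------
    @classmethod
    def proportional_hazards(cls, baseline: BaselineParams, beta) -> "GHModel":
        """PH model: alpha = 0 (implemented as no time-level covariates)."""
        return cls(baseline, alpha=(), beta=tuple(np.atleast_1d(beta)), time_index=())

    @classmethod
    def accelerated_failure_time(cls, baseline: BaselineParams, coef) -> "GHModel":
        """AFT model: w = x and alpha = beta."""
        coef = tuple(np.atleast_1d(coef))
        return cls(baseline, alpha=coef, beta=coef, time_index=tuple(range(len(coef))))

    @classmethod
    def accelerated_hazards(cls, baseline: BaselineParams, alpha) -> "GHModel":
        """AH model: beta = 0 with all covariates on the time scale."""
        alpha = tuple(np.atleast_1d(alpha))
        return cls(baseline, alpha=alpha, beta=(0.0,) * len(alpha), time_index=tuple(range(len(alpha))))

    @property
    def n_covariates(self) -> int:
        return len(self.beta)

    @property
    def is_ph(self) -> bool:
        return all(a == 0 for a in self.alpha) or not self.alpha

    @property
    def is_ah(self) -> bool:
        return all(b == 0 for b in self.beta)

    @property
    def is_aft(self) -> bool:
        return (
            self.time_index == tuple(range(len(self.beta)))
            and self.alpha == self.beta
        )

    # -- linear predictors ----------------------------------------------
    def _check_x(self, x) -> np.ndarray:
        X = np.atleast_2d(np.asarray(x, dtype=float))
        if X.shape[1] != len(self.beta):
            raise ValueError(f"expected {len(self.beta)} covariates, got {X.shape[1]}")
        return X

    def linear_predictors(self, x):
        """Return (eta_t, eta_h) = (w'alpha, x'beta), each of shape (n,)."""
        X = self._check_x(x)
        if self.time_index:
            eta_t = X[:, list(self.time_index)] @ np.asarray(self.alpha)
        else:
            eta_t = np.zeros(X.shape[0])
        eta_h = X @ np.asarray(self.beta) if self.beta else np.zeros(X.shape[0])
        return eta_t, eta_h

    # -- hazard machinery -----------------------------------------------
    def excess_hazard(self, t, x):
        """hE(t; x).  ``x`` may be one covariate vector (broadcast over the
        time grid ``t``) or an (n, p) matrix paired elementwise with ``t``."""
        eta_t, eta_h = self.linear_predictors(x)
        t = np.asarray(t, dtype=float)
        single = np.atleast_2d(np.asarray(x)).shape[0] == 1
        if single:
            out = bl.hazard(self.baseline, t * np.exp(eta_t[0])) * np.exp(eta_h[0])
        else:
            out = bl.hazard(self.baseline, t * np.exp(eta_t)) * np.exp(eta_h)
        return out

    def excess_cum_hazard(self, t, x):
        """HE(t; x) with the same broadcasting rules as ``excess_hazard``."""
        eta_t, eta_h = self.linear_predictors(x)
        t = np.asarray(t, dtype=float)
        single = np.atleast_2d(np.asarray(x)).shape[0] == 1
        if single:
            out = bl.cum_hazard(self.baseline, t * np.exp(eta_t[0])) * np.exp(eta_h[0] - eta_t[0])
        else:
            out = bl.cum_hazard(self.baseline, t * np.exp(eta_t)) * np.exp(eta_h - eta_t)
        return out

    def cum_hazard_matrix(self, t_grid, X) -> np.ndarray:
        """HE(t_j; x_i) as an (n, T) matrix, used by net-survival averaging."""
        eta_t, eta_h = self.linear_predictors(X)
        tt = np.asarray(t_grid, dtype=float)[None, :] * np.exp(eta_t)[:, None]
        H0 = bl.cum_hazard(self.baseline, tt)
        return H0 * np.exp(eta_h - eta_t)[:, None]

    # -- simulation ------------------------------------------------------
    def simulate_event_time(self, x, u, frailty=1.0):
        """Exact inverse-transform draw of an event time.

        Solves ``frailty * HE(t; x) = -log(1 - u)`` for t, i.e.

            t = F0^{-1}(1 - exp{log(1-u) exp(w'alpha - x'beta) / frailty}) * exp(-w'alpha).

        ``u`` must lie in [0, 1); ``frailty`` must be positive.
        """
        u_arr = np.asarray(u, dtype=float)
        if np.any(~np.isfinite(u_arr)) or np.any(u_arr < 0) or np.any(u_arr >= 1):
            raise ValueError("u must lie in [0, 1)")
        lam = np.asarray(frailty, dtype=float)
        if np.any(lam <= 0):
            raise ValueError("frailty must be positive")
        eta_t, eta_h = self.linear_predictors(x)
        single = np.atleast_2d(np.asarray(x)).shape[0] == 1
        if single and u_arr.ndim > 0:
            eta_t = np.full_like(u_arr, eta_t[0])
            eta_h = np.full_like(u_arr, eta_h[0])
        target = -np.log1p(-u_arr) * np.exp(eta_t - eta_h) / lam
        t = bl.inv_cum_hazard(self.baseline, target) * np.exp(-eta_t)
        if np.isscalar(u) and np.ndim(t) > 0 and np.size(t) == 1:
            return float(np.asarray(t).ravel()[0])
        return t

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "baseline": self.baseline.to_dict(),
            "alpha": list(self.alpha),
            "beta": list(self.beta),
            "time_index": list(self.time_index),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GHModel":
        return cls(
            baseline=BaselineParams.from_dict(d["baseline"]),
            alpha=tuple(d.get("alpha", ())),
            beta=tuple(d.get("beta", ())),
            time_index=tuple(d.get("time_index", ())),
        )
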