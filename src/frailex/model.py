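"""Maximum-likelihood inference for excess hazard models.

The observed-data log-likelihood drops the parameter-free population
survival factor, so only the population rate at the observed time enters.
For the classical (no-frailty) model

    l(psi) = sum_i [ delta_i log(hP_i + hE_i) - HE_i ],

and for the gamma-frailty model

    l(psi) = sum_i [ delta_i log(hP_i + hE_i / (1 + b HE_i))
                     - (1/b) log(1 + b HE_i) ].

Optimization is over an unconstrained transform: log(sigma), log(nu),
log(gamma), log(b) and raw regression coefficients.  Standard errors come
from the numerical Hessian on that transformed scale; confidence intervals
for positive parameters are formed on the log scale and exponentiated,
coefficient intervals on the natural scale.  The default initialization
fits a classical proportional-hazards model first and seeds the full model
from it (time-level effects start at the PH hazard-level estimates, the
frailty variance starts at 1).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_fprime, approx_hess

from . import baseline as bl
from .baseline import BaselineParams
from .frailty import FrailtySpec
from .gh import GHModel
from .lifetables import CohortData, LifeTable
from .netsurv import NetSurvivalCurve, default_grid, population_net_survival

__all__ = [
    "ParamVector",
    "ParamTemplate",
    "ExcessHazardModel",
    "ExcessHazardResults",
    "loglik_classical",
    "loglik_frailty",
    "aic_compare",
]

_BAD_LOGLIK = -1e10  # optimizer-safe stand-in for -inf
_B_TINY = 1e-10


@dataclass
class ParamVector:
    """Full parameter set psi = (theta, alpha, beta[, b])."""

    baseline: BaselineParams
    alpha: np.ndarray
    beta: np.ndarray
    b: float | None = None

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float)) if np.size(self.alpha) else np.zeros(0)
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float)) if np.size(self.beta) else np.zeros(0)
        if self.b is not None:
            if not np.isfinite(self.b) or self.b < 0:
                raise ValueError("frailty variance b must be nonnegative")
            self.b = float(self.b)

    @property
    def k(self) -> int:
        """Number of free parameters."""
        return self.baseline.n_params + self.alpha.size + self.beta.size + (self.b is not None)


@dataclass(frozen=True)
class ParamTemplate:
    """Layout of the flat (transformed) parameter vector.

    Order: log-baseline parameters, alpha, beta, then log(b) if the model
    has a frailty.  pack/unpack round-trip is the identity.
    """

    family: str
    n_time: int
    n_cov: int
    has_frailty: bool
    names: tuple = ()
    time_index: tuple = ()

    @property
    def n_baseline(self) -> int:
        return 2 if self.family in ("lognormal", "loglogistic") else 3

    @property
    def k(self) -> int:
        return self.n_baseline + self.n_time + self.n_cov + int(self.has_frailty)

    @property
    def param_names(self) -> tuple:
        base = ("sigma", "nu") if self.n_baseline == 2 else ("sigma", "nu", "gamma")
        cov = self.names if self.names else tuple(f"x{j+1}" for j in range(self.n_cov))
        a = tuple(f"alpha_{cov[i]}" for i in self.time_index)
        b = tuple(f"beta_{c}" for c in cov)
        return base + a + b + (("b",) if self.has_frailty else ())

    @property
    def is_log_scale(self) -> np.ndarray:
        """Mask of parameters optimized (and CI'd) on the log scale."""
        return np.array(
            [True] * self.n_baseline
            + [False] * (self.n_time + self.n_cov)
            + ([True] if self.has_frailty else [])
        )

    def pack(self, psi: ParamVector) -> np.ndarray:
        nb = self.n_baseline
        head = [np.log(psi.baseline.sigma), np.log(psi.baseline.nu)]
        if nb == 3:
            head.append(np.log(psi.baseline.gamma))
        tail = [np.log(psi.b)] if self.has_frailty else []
        if self.has_frailty and psi.b is None:
            raise ValueError("template expects a frailty variance b")
        return np.concatenate([head, psi.alpha, psi.beta, tail])

    def unpack(self, vec: np.ndarray) -> ParamVector:
        vec = np.asarray(vec, dtype=float)
        if vec.size != self.k:
            raise ValueError(f"expected {self.k} parameters, got {vec.size}")
        # keep exponentiated parameters finite for extreme (e.g. MC) draws
        vec = np.where(self.is_log_scale, np.clip(vec, -300.0, 300.0), vec)
        nb = self.n_baseline
        base = BaselineParams(
            family=self.family,
            sigma=float(np.exp(vec[0])),
            nu=float(np.exp(vec[1])),
            gamma=float(np.exp(vec[2])) if nb == 3 else 1.0,
        )
        alpha = vec[nb : nb + self.n_time]
        beta = vec[nb + self.n_time : nb + self.n_time + self.n_cov]
        b = float(np.exp(vec[-1])) if self.has_frailty else None
        return ParamVector(base, alpha, beta, b)

    def natural(self, vec: np.ndarray) -> np.ndarray:
        """Map a transformed vector to the natural scale."""
        out = np.asarray(vec, dtype=float).copy()
        with np.errstate(over="ignore"):
            out[self.is_log_scale] = np.exp(out[self.is_log_scale])
        return out


# ---------------------------------------------------------------------------
def _hazard_parts(psi: ParamVector, time, X, time_index):
    """(log hE, HE) for every row; vectorized."""
    if time_index:
        eta_t = X[:, list(time_index)] @ psi.alpha
    else:
        eta_t = np.zeros(X.shape[0])
    eta_h = X @ psi.beta if psi.beta.size else np.zeros(X.shape[0])
    with np.errstate(all="ignore"):
        tt = time * np.exp(eta_t)
        logts = np.log(tt) - np.log(psi.baseline.sigma)
        p = psi.baseline
        if p.family == "pgw":
            y = p.nu * logts
            logh0 = (
                np.log(p.nu) - np.log(p.gamma) - np.log(p.sigma)
                + (p.nu - 1.0) * logts
                + (1.0 / p.gamma - 1.0) * np.logaddexp(0.0, y)
            )
            H0 = np.expm1(np.logaddexp(0.0, y) / p.gamma)
        else:
            logh0 = bl.log_hazard(p, np.maximum(tt, 1e-300))
            H0 = bl.cum_hazard(p, tt)
        log_hE = logh0 + eta_h
        HE = H0 * np.exp(eta_h - eta_t)
    return log_hE, HE


def _loglik(psi: ParamVector, data: CohortData, hp_obs: np.ndarray, time_index, frailty: bool) -> float:
    log_hE, HE = _hazard_parts(psi, data.time, data.covariates, time_index)
    delta = data.status.astype(bool)
    b = psi.b if (frailty and psi.b is not None) else 0.0
    with np.errstate(all="ignore"):
        if b > _B_TINY:
            log1pbH = np.log1p(b * HE)
            death_terms = np.log(hp_obs[delta] + np.exp(log_hE[delta] - log1pbH[delta]))
            ll = death_terms.sum() - log1pbH.sum() / b
        else:
            death_terms = np.log(hp_obs[delta] + np.exp(log_hE[delta]))
            ll = death_terms.sum() - HE.sum()
    return float(ll) if np.isfinite(ll) else -np.inf


def _pop_hazard_at_exit(data: CohortData, lt: LifeTable) -> np.ndarray:
    """hP(age_i + t_i; year_i + t_i, z_i) for every individual (precomputed
    once per dataset: the cumulative population term never enters the fit)."""
    ages = data.age + data.time
    years = data.year + data.time
    if lt.strata_cols:
        if data.strata is None:
            raise ValueError(
                f"life table is stratified by {lt.strata_cols} but the cohort carries no strata"
            )
        out = np.empty(data.n)
        strata = np.asarray(data.strata)
        for key in np.unique(strata):
            m = strata == key
            out[m] = lt.pop_hazard(ages[m], years[m], key)
        return out
    return np.asarray(lt.pop_hazard(ages, years))


def loglik_classical(psi: ParamVector, data: CohortData, lt: LifeTable, time_index=()) -> float:
    """Log-likelihood of the model without frailty (up to the dropped
    population survival constant)."""
    return _loglik(psi, data, _pop_hazard_at_exit(data, lt), tuple(time_index), frailty=False)


def loglik_frailty(psi: ParamVector, data: CohortData, lt: LifeTable, time_index=()) -> float:
    """Log-likelihood of the gamma-frailty model (marginal over frailties)."""
    return _loglik(psi, data, _pop_hazard_at_exit(data, lt), tuple(time_index), frailty=True)


# ---------------------------------------------------------------------------
class ExcessHazardModel:
    """Excess hazard regression model against life-table background mortality.

    Parameters
    ----------
    data : CohortData
        Individual records (time, status, covariates, age, year, strata).
    lifetable : LifeTable
        Expected population mortality rates.
    baseline : str
        Baseline hazard family: "pgw" (default), "lognormal", "loglogistic".
    frailty : str or None
        "gamma" for the gamma-frailty model, None/"none" for the classical
        model.  (An "inverse_gaussian" frailty is accepted as well.)
    time_index : sequence of int or None
        Covariate columns with time-level effects (the GH ``w``); default
        is all columns.  Pass ``()`` for a proportional-hazards model.
    """

    def __init__(self, data: CohortData, lifetable: LifeTable, baseline: str = "pgw",
                 frailty: str | None = "gamma", time_index=None):
        if data.n_events < 1:
            raise ValueError("at least one event is required to fit")
        self.data = data
        self.lifetable = lifetable
        if frailty in (None, "none"):
            frailty = None
        elif frailty not in ("gamma", "inverse_gaussian"):
            raise ValueError(f"unsupported frailty {frailty!r}")
        self.frailty_family = frailty
        if time_index is None:
            time_index = tuple(range(data.covariates.shape[1]))
        self.time_index = tuple(int(i) for i in time_index)
        self.template = ParamTemplate(
            family=baseline,
            n_time=len(self.time_index),
            n_cov=data.covariates.shape[1],
            has_frailty=frailty is not None,
            names=data.names,
            time_index=self.time_index,
        )
        self._hp_obs = _pop_hazard_at_exit(data, lifetable)
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(data.n), data.covariates]))
        if rank < data.covariates.shape[1] + 1:
            warnings.warn("covariate matrix (plus intercept) is rank deficient", stacklevel=2)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, lifetable: LifeTable, hazard_covs,
                       time_covs=None, baseline: str = "pgw", frailty: str | None = "gamma",
                       time_col="time", status_col="status", age_col="age", year_col="year",
                       strata_col=None) -> "ExcessHazardModel":
        """Build a model from a tidy DataFrame.

        ``hazard_covs`` are the columns of x; ``time_covs`` (a subset of
        ``hazard_covs``; default all of them) select the GH time-level
        covariates w.
        """
        hazard_covs = list(hazard_covs)
        if time_covs is None:
            time_covs = hazard_covs
        missing = [c for c in time_covs if c not in hazard_covs]
        if missing:
            raise ValueError(f"time covariates {missing} are not among the hazard covariates")
        data = CohortData.from_dataframe(
            df, hazard_covs, time_col=time_col, status_col=status_col,
            age_col=age_col, year_col=year_col, strata_col=strata_col,
        )
        time_index = tuple(hazard_covs.index(c) for c in time_covs)
        return cls(data, lifetable, baseline=baseline, frailty=frailty, time_index=time_index)

    # -- likelihood ------------------------------------------------------
    def loglike(self, psi: ParamVector) -> float:
        return _loglik(psi, self.data, self._hp_obs, self.time_index, self.frailty_family is not None)

    def _nll(self, vec: np.ndarray) -> float:
        try:
            ll = self.loglike(self.template.unpack(vec))
        except (ValueError, FloatingPointError):
            return -_BAD_LOGLIK
        return -ll if np.isfinite(ll) else -_BAD_LOGLIK

    # -- initialization --------------------------------------------------
    def _neutral_init(self) -> ParamVector:
        t_events = self.data.time[self.data.status == 1]
        sigma0 = float(np.clip(np.median(t_events), 0.05, 50.0))
        base = BaselineParams(self.template.family, sigma=sigma0, nu=1.0, gamma=1.0)
        return ParamVector(
            base,
            np.zeros(self.template.n_time),
            np.zeros(self.template.n_cov),
            1.0 if self.frailty_family else None,
        )

    def _default_init(self) -> ParamVector:
        """Classical-PH initialization: fit the no-frailty PH model, seed the
        time-level effects from its hazard-level estimates and b from 1."""
        if self.frailty_family is None and not self.time_index:
            return self._neutral_init()
        ph = ExcessHazardModel(
            self.data, self.lifetable, baseline=self.template.family,
            frailty=None, time_index=(),
        )
        ph_fit = ph.fit(init=ph._neutral_init(), _hessian=False)
        est = ph_fit.params_object
        alpha0 = est.beta[list(self.time_index)] if self.time_index else np.zeros(0)
        return ParamVector(
            est.baseline, alpha0, est.beta, 1.0 if self.frailty_family else None
        )

    def _newton_polish(self, x: np.ndarray, fval: float, max_steps: int = 4):
        """Damped Newton refinement after the quasi-Newton run: L-BFGS-B
        stops on a relative-f criterion, which for likelihoods of magnitude
        ~1e4 can leave a gradient of order 1e-2; a couple of Newton steps
        with the numerical Hessian tightens the stationary point."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(max_steps):
                g = approx_fprime(x, self._nll, centered=True)
                if not np.all(np.isfinite(g)) or np.max(np.abs(g)) < 1e-6:
                    break
                H = approx_hess(x, self._nll)
                if not np.all(np.isfinite(H)):
                    break
                try:
                    step = np.linalg.solve(H, g)
                except np.linalg.LinAlgError:
                    break
                improved = False
                for damp in (1.0, 0.5, 0.25, 0.1):
                    cand = x - damp * step
                    fc = self._nll(cand)
                    if fc < fval:
                        x, fval, improved = cand, fc, True
                        break
                if not improved:
                    break
        return x, fval

    # -- fitting ---------------------------------------------------------
    def fit(self, init: ParamVector | None = None, level: float = 0.95,
            maxiter: int = 500, _hessian: bool = True) -> "ExcessHazardResults":
        """Maximize the log-likelihood; returns an :class:`ExcessHazardResults`.

        ``init`` is a starting :class:`ParamVector`; by default the
        classical-PH initialization strategy is used.
        """
        psi0 = self._default_init() if init is None else init
        x0 = self.template.pack(psi0)
        opt = optimize.minimize(
            self._nll, x0, method="L-BFGS-B",
            options={"maxiter": maxiter, "maxfun": 20 * maxiter, "ftol": 1e-11, "gtol": 1e-7},
        )
        xhat, fval = self._newton_polish(opt.x, float(opt.fun))
        llf = -fval
        converged = bool(opt.success) and llf > _BAD_LOGLIK / 2
        message = str(opt.message)
        cov = None
        if _hessian and converged:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                H = approx_hess(xhat, self._nll)
            if not np.all(np.isfinite(H)):
                converged, message = False, "non-finite Hessian entries"
            else:
                try:
                    cov = np.linalg.inv(H)
                except np.linalg.LinAlgError:
                    converged, message = False, "singular Hessian"
                if cov is not None and np.any(np.diag(cov) <= 0):
                    converged, message = False, "Hessian not positive definite"
        return ExcessHazardResults(
            model=self, params_tx=xhat, cov_tx=cov, llf=llf,
            converged=converged, message=message, level=level, nit=int(opt.nit),
        )


# ---------------------------------------------------------------------------
class ExcessHazardResults:
    """Fit results: estimates, covariance, intervals, AIC, diagnostics."""

    def __init__(self, model, params_tx, cov_tx, llf, converged, message, level, nit=0,
                 template: ParamTemplate | None = None):
        self.model = model
        self.template = template if template is not None else model.template
        self.params_tx = np.asarray(params_tx, dtype=float)
        self.cov_tx = None if cov_tx is None else np.asarray(cov_tx, dtype=float)
        self.llf = float(llf)
        self.converged = bool(converged)
        self.message = message
        self.level = float(level)
        self.nit = nit
        self.params_object = self.template.unpack(self.params_tx)
        self.param_names = self.template.param_names
        self.n_obs = model.data.n if model is not None else None
        self.n_events = model.data.n_events if model is not None else None
        self._frailty_family = model.frailty_family if model is not None else (
            "gamma" if self.template.has_frailty else None)

    # -- core quantities -------------------------------------------------
    @property
    def params(self) -> np.ndarray:
        """Estimates on the natural scale."""
        return self.template.natural(self.params_tx)

    @property
    def k(self) -> int:
        return self.template.k

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.llf

    @property
    def bse_tx(self) -> np.ndarray:
        if self.cov_tx is None:
            return np.full(self.k, np.nan)
        return np.sqrt(np.diag(self.cov_tx))

    @property
    def bse(self) -> np.ndarray:
        """Natural-scale standard errors (delta method for log-scale
        parameters: se(exp(u)) = exp(u) * se(u))."""
        se = self.bse_tx.copy()
        logm = self.template.is_log_scale
        se[logm] = se[logm] * self.params[logm]
        return se

    def conf_int(self, level: float | None = None) -> pd.DataFrame:
        """Wald intervals: log-scale-and-exponentiate for positive
        parameters, natural scale for regression coefficients."""
        level = self.level if level is None else level
        z = stats.norm.ppf(1 - (1 - level) / 2)
        lo_tx = self.params_tx - z * self.bse_tx
        hi_tx = self.params_tx + z * self.bse_tx
        lo = self.template.natural(lo_tx)
        hi = self.template.natural(hi_tx)
        return pd.DataFrame({"lower": lo, "upper": hi}, index=list(self.param_names))

    @property
    def gh(self) -> GHModel:
        psi = self.params_object
        return GHModel(psi.baseline, alpha=psi.alpha, beta=psi.beta,
                       time_index=self.template.time_index)

    @property
    def frailty_spec(self) -> FrailtySpec | None:
        psi = self.params_object
        if psi.b is None:
            return None
        return FrailtySpec(family=self._frailty_family or "gamma", b=psi.b)

    def score_tx(self) -> np.ndarray:
        """Numerical gradient of the log-likelihood at the estimate, on the
        transformed scale (a convergence diagnostic; near zero at an
        interior optimum)."""
        if self.model is None:
            raise ValueError("no model attached")
        return -approx_fprime(self.params_tx, self.model._nll, centered=True)

    # -- net survival ----------------------------------------------------
    def net_survival(self, t_grid=None, X=None, mask=None, group=None) -> NetSurvivalCurve:
        """Population (or subgroup) net survival at the fitted parameters."""
        if X is None:
            if self.model is None:
                raise ValueError("no data attached; pass a covariate matrix X")
            X = self.model.data.covariates
        return population_net_survival(self.gh, self.frailty_spec, X, t_grid, mask=mask, group=group)

    def mc_ci_net_survival(self, t_grid=None, X=None, mask=None, n_draws: int = 1000,
                           seed=None, level: float | None = None) -> pd.DataFrame:
        """Monte-Carlo pointwise CI for the net-survival curve.

        Draws parameter vectors from N(psi_hat, J^{-1}) on the transformed
        scale, recomputes the curve per draw, and reports the empirical
        (1-level)/2 and 1-(1-level)/2 quantiles.
        """
        if not self.converged or self.cov_tx is None:
            raise ValueError("Monte-Carlo intervals need a converged fit with a covariance")
        level = self.level if level is None else level
        t_grid = default_grid() if t_grid is None else np.asarray(t_grid, dtype=float)
        if X is None:
            X = self.model.data.covariates
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if mask is not None:
            X = X[np.asarray(mask, dtype=bool)]
        cov = self.cov_tx
        eigval, eigvec = np.linalg.eigh((cov + cov.T) / 2)
        if eigval.min() < -1e-10:
            warnings.warn("covariance not PSD; clipping negative eigenvalues", stacklevel=2)
        eigval = np.clip(eigval, 0.0, None)
        L = eigvec * np.sqrt(eigval)
        rng = np.random.default_rng(seed)
        zs = rng.standard_normal((n_draws, self.k))
        draws = self.params_tx + zs @ L.T
        curves = np.empty((n_draws, t_grid.size))
        for i, vec in enumerate(draws):
            psi = self.template.unpack(vec)
            gh = GHModel(psi.baseline, psi.alpha, psi.beta, self.template.time_index)
            fr = None if psi.b is None else FrailtySpec(self._frailty_family or "gamma", psi.b)
            HE = gh.cum_hazard_matrix(t_grid, X)
            if fr is None or fr.effective_b == 0.0:
                curves[i] = np.exp(-HE).mean(axis=0)
            else:
                curves[i] = fr.marginal_net_survival(HE).mean(axis=0)
        point = self.net_survival(t_grid, X=X).values
        a = (1 - level) / 2
        lower = np.minimum(np.quantile(curves, a, axis=0), point)
        upper = np.maximum(np.quantile(curves, 1 - a, axis=0), point)
        return pd.DataFrame({"t": t_grid, "estimate": point, "lower": lower, "upper": upper})

    # -- reporting -------------------------------------------------------
    def estimates_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {"estimate": self.params, "se": self.bse, "lower": ci["lower"], "upper": ci["upper"]},
            index=list(self.param_names),
        )

    def summary(self) -> str:
        frailty = self._frailty_family
        lines = [
            "Excess hazard model (general hazard structure)",
            "=" * 62,
            f"Baseline family:      {self.template.family}",
            f"Frailty:              {frailty or 'none (classical model)'}",
            f"No. observations:     {self.n_obs}    events: {self.n_events}",
            f"Log-likelihood:       {self.llf:.3f}",
            f"AIC:                  {self.aic:.2f}",
            f"Converged:            {self.converged} ({self.message})",
            "-" * 62,
            f"{'parameter':<14}{'estimate':>10}{'std err':>10}"
            f"{f'[{self.level:.0%} conf. interval]':>24}",
        ]
        est = self.estimates_frame()
        for name, row in est.iterrows():
            lines.append(
                f"{name:<14}{row['estimate']:>10.4f}{row['se']:>10.4f}"
                f"{row['lower']:>12.4g}{row['upper']:>12.4g}"
            )
        lines.append("=" * 62)
        return "\n".join(lines)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "template": {
                "family": self.template.family,
                "n_time": self.template.n_time,
                "n_cov": self.template.n_cov,
                "has_frailty": self.template.has_frailty,
                "names": list(self.template.names),
                "time_index": list(self.template.time_index),
            },
            "frailty_family": self._frailty_family,
            "params_tx": self.params_tx.tolist(),
            "cov_tx": None if self.cov_tx is None else self.cov_tx.tolist(),
            "llf": self.llf,
            "aic": self.aic,
            "converged": self.converged,
            "message": self.message,
            "level": self.level,
            "n_obs": self.n_obs,
            "n_events": self.n_events,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "ExcessHazardResults":
        t = d["template"]
        template = ParamTemplate(
            family=t["family"], n_time=t["n_time"], n_cov=t["n_cov"],
            has_frailty=t["has_frailty"], names=tuple(t["names"]),
            time_index=tuple(t["time_index"]),
        )
        out = cls(
            model=None, params_tx=np.asarray(d["params_tx"]),
            cov_tx=None if d["cov_tx"] is None else np.asarray(d["cov_tx"]),
            llf=d["llf"], converged=d["converged"], message=d["message"],
            level=d["level"], template=template,
        )
        out.n_obs = d.get("n_obs")
        out.n_events = d.get("n_events")
        out._frailty_family = d.get("frailty_family")
        return out

    @classmethod
    def load(cls, path) -> "ExcessHazardResults":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def aic_compare(fits) -> pd.DataFrame:
    """Rank fits of the same data by AIC (ascending; ties favour fewer
    parameters).  Raises if the fits are not on identical data."""
    fits = list(fits)
    keys = {(f.n_obs, f.n_events) for f in fits}
    if len(keys) > 1:
        raise ValueError("AIC comparison requires fits on identical data")
    rows = [
        {
            "model": ("frailty" if f.template.has_frailty else "classical") + f"-{f.template.family}",
            "k": f.k,
            "loglik": f.llf,
            "aic": f.aic,
        }
        for f in fits
    ]
    out = pd.DataFrame(rows).sort_values(["aic", "k"], kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
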