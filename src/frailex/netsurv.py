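"""Net survival: individual, subgroup, and population curves.

The classical net survival is ``SN(t; x) = exp(-HE(t; x))``; under a frailty
model the marginal net survival is the Laplace transform of the frailty
distribution at HE (for the gamma frailty, ``1 / (1 + b HE)^(1/b)``).
Population and subgroup curves are unweighted averages of individual curves
over the corresponding rows of the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frailty import FrailtySpec
from .gh import GHModel

__all__ = ["NetSurvivalCurve", "default_grid", "individual_net_survival", "population_net_survival"]


def default_grid(stop: float = 5.0, step: float = 0.05) -> np.ndarray:
    """Default evaluation grid: 0 to the 5-year study horizon in 0.05 steps."""
    return np.round(np.arange(0.0, stop + step / 2, step), 10)


@dataclass
class NetSurvivalCurve:
    """A net-survival curve on a time grid.

    variant is "classical" (exp(-HE)) or "frailty_marginal" (Laplace
    transform of the frailty at HE); scope records whether the curve refers
    to an individual covariate profile, a subgroup average, or the
    population average.
    """

    t: np.ndarray
    values: np.ndarray
    variant: str = "classical"
    scope: str = "individual"
    group: str | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t.size != self.values.size:
            raise ValueError("t and values must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t grid must be strictly increasing")
        if np.any(self.values > 1 + 1e-12) or np.any(self.values < 0):
            raise ValueError("survival values must lie in [0, 1]")
        if np.any(np.diff(self.values) > 1e-10):
            raise ValueError("survival values must be nonincreasing")

    def __call__(self, t):
        return np.interp(t, self.t, self.values)

    def plot(self, ax=None, **kwargs):
        """Plot the curve (requires matplotlib); returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        label = kwargs.pop("label", f"{self.variant} ({self.scope})")
        ax.plot(self.t, self.values, label=label, **kwargs)
        ax.set_xlabel("years since diagnosis")
        ax.set_ylabel("net survival")
        ax.set_ylim(0, 1.02)
        return ax


def individual_net_survival(gh: GHModel, frailty: FrailtySpec | None, x, t_grid=None) -> NetSurvivalCurve:
    """Net survival for a single covariate profile ``x``.

    With ``frailty=None`` (or family "none" / b=0) this is the classical
    ``exp(-HE(t; x))``; otherwise the frailty-marginal version.
    """
    t_grid = default_grid() if t_grid is None else np.asarray(t_grid, dtype=float)
    HE = gh.excess_cum_hazard(t_grid, np.atleast_1d(x))
    if frailty is None or frailty.effective_b == 0.0:
        values = np.exp(-HE)
        variant = "classical"
    else:
        values = frailty.marginal_net_survival(HE)
        variant = "frailty_marginal"
    return NetSurvivalCurve(t_grid, values, variant=variant, scope="individual")


def population_net_survival(
    gh: GHModel,
    frailty: FrailtySpec | None,
    X,
    t_grid=None,
    mask=None,
    group: str | None = None,
) -> NetSurvivalCurve:
    """Average of individual net-survival curves over the rows of ``X``.

    ``mask`` restricts the average to a subgroup (boolean row selector);
    an empty subgroup is an error.
    """
    t_grid = default_grid() if t_grid is None else np.asarray(t_grid, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if mask is not None:
        X = X[np.asarray(mask, dtype=bool)]
        scope = "subgroup"
    else:
        scope = "population" if X.shape[0] > 1 else "individual"
    if X.shape[0] == 0:
        raise ValueError("empty subgroup: no rows selected")
    HE = gh.cum_hazard_matrix(t_grid, X)  # (n, T)
    if frailty is None or frailty.effective_b == 0.0:
        values = np.exp(-HE).mean(axis=0)
        variant = "classical"
    else:
        values = frailty.marginal_net_survival(HE).mean(axis=0)
        variant = "frailty_marginal"
    return NetSurvivalCurve(t_grid, values, variant=variant, scope=scope, group=group)
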