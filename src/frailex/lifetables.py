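"""Expected (population) mortality from life tables, and cohort containers.

A life table is a grid of all-cause mortality rates (deaths per person-year)
indexed by integer attained age and integer calendar year, optionally
stratified by demographic labels such as sex.  During follow-up both the
attained age and the calendar year advance with time since diagnosis, so the
population hazard experienced by an individual is piecewise constant on
1-year x 1-year Lexis squares.  Cell addressing uses the floor of attained
age and of attained calendar time; lookups above the covered range are
capped at the oldest age / latest year (never extrapolated downward), and
lookups below the range raise.

The module also provides exact simulation of other-cause death times by
inverting the piecewise-exponential survival function, a long-format
delimited reader/writer, and a synthetic Gompertz-shaped "UK-like" table
generator used as the test substrate (national life tables are not
redistributable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "CohortData",
    "make_gompertz_lifetable",
    "read_lifetable",
    "write_lifetable",
]

# nudge used in cell addressing so that boundary ages/years created by exact
# arithmetic (age + t landing on an integer) fall in the cell they open
_EPS = 1e-9


class LifeTable:
    """Gridded population mortality rates with Lexis-square semantics.

    Parameters
    ----------
    frame : pandas.DataFrame
        Long format with columns ``age`` (int), ``year`` (int), ``rate``
        (nonnegative, deaths per person-year) and any further columns
        treated as stratification labels.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        required = {"age", "year", "rate"}
        if not required.issubset(frame.columns):
            raise ValueError(f"life table needs columns {sorted(required)}")
        self.strata_cols = [c for c in frame.columns if c not in required]
        if (frame["rate"] < 0).any() or not np.isfinite(frame["rate"]).all():
            raise ValueError("life-table rates must be finite and nonnegative")
        self._grids: dict[tuple, np.ndarray] = {}
        groups = frame.groupby(self.strata_cols) if self.strata_cols else [((), frame)]
        age_range = year_range = None
        for key, g in groups:
            key = key if isinstance(key, tuple) else (key,)
            a0, a1 = int(g["age"].min()), int(g["age"].max())
            y0, y1 = int(g["year"].min()), int(g["year"].max())
            expect = (a1 - a0 + 1) * (y1 - y0 + 1)
            if len(g) != expect or g.duplicated(["age", "year"]).any():
                raise ValueError(f"life-table stratum {key} is not a contiguous age x year grid")
            if age_range is None:
                age_range, year_range = (a0, a1), (y0, y1)
            elif (a0, a1) != age_range or (y0, y1) != year_range:
                raise ValueError("all strata must cover the same age and year ranges")
            grid = np.full((a1 - a0 + 1, y1 - y0 + 1), np.nan)
            grid[g["age"].to_numpy() - a0, g["year"].to_numpy() - y0] = g["rate"].to_numpy(float)
            self._grids[key] = grid
        self.age_min, self.age_max = age_range
        self.year_min, self.year_max = year_range
        self._frame = frame

    # ------------------------------------------------------------------
    def _key(self, strata) -> tuple:
        if strata is None:
            key = ()
        elif isinstance(strata, dict):
            key = tuple(strata[c] for c in self.strata_cols)
        elif isinstance(strata, (tuple, list)):
            key = tuple(strata)
        else:
            key = (strata,)
        if key not in self._grids:
            raise KeyError(f"unknown life-table stratum {key!r}")
        return key

    def _cells(self, age, year):
        a = np.floor(np.asarray(age, dtype=float) + _EPS).astype(int)
        y = np.floor(np.asarray(year, dtype=float) + _EPS).astype(int)
        if np.any(a < self.age_min) or np.any(y < self.year_min):
            raise ValueError(
                f"age/year below life-table start (age >= {self.age_min}, year >= {self.year_min})"
            )
        return np.minimum(a, self.age_max) - self.age_min, np.minimum(y, self.year_max) - self.year_min

    def pop_hazard(self, age, year, strata=None):
        """Population rate hP of the 1x1 Lexis cell containing (age, year)."""
        grid = self._grids[self._key(strata)]
        ai, yi = self._cells(age, year)
        out = grid[ai, yi]
        return float(out) if np.isscalar(age) and np.isscalar(year) else out

    def cum_hazard_increment(self, age, year, t, strata=None):
        """HP(age+t; year+t) - HP(age; year): the cumulative population
        hazard accrued over ``t`` years of follow-up, integrating the
        piecewise-constant rate while age and year advance together."""
        grid = self._grids[self._key(strata)]
        age = np.asarray(age, dtype=float)
        year = np.asarray(year, dtype=float)
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("t must be nonnegative")
        scalar = age.ndim == 0 and year.ndim == 0 and t.ndim == 0
        age, year, t = np.broadcast_arrays(np.atleast_1d(age), np.atleast_1d(year), np.atleast_1d(t))
        s = np.zeros(age.shape)
        H = np.zeros(age.shape)
        while True:
            active = s < t - 1e-15
            if not np.any(active):
                break
            a = age + s
            y = year + s
            ai, yi = self._cells(a, y)
            rate = grid[ai, yi]
            step_a = np.floor(a + _EPS) + 1.0 - a
            step_y = np.floor(y + _EPS) + 1.0 - y
            ds = np.minimum(np.minimum(step_a, step_y), t - s)
            ds = np.where(active, np.maximum(ds, 0.0), 0.0)
            H += rate * ds
            s += ds
        return float(H[0]) if scalar else H

    # ------------------------------------------------------------------
    def simulate_other_cause_time(self, age, year, strata=None, u=None, horizon=None):
        """Exact inversion of the piecewise-exponential other-cause survival.

        Returns T with ``cum_hazard_increment(age, year, T) = -log(u)``;
        S(T) = u, so small u means long survival.  If ``horizon`` is given
        and the solution exceeds it, ``inf`` is returned (administrative
        censoring is applied downstream).  Beyond the table range the capped
        (oldest-age, latest-year) rate applies indefinitely.
        """
        if u is None or not (0 < u < 1):
            raise ValueError("u must lie in (0, 1)")
        grid = self._grids[self._key(strata)]
        target = -np.log(u)
        s, H = 0.0, 0.0
        while True:
            if horizon is not None and s >= horizon:
                return np.inf
            a, y = age + s, year + s
            ai, yi = self._cells(np.asarray(a), np.asarray(y))
            rate = float(grid[int(ai), int(yi)])
            capped = (np.floor(a + _EPS) >= self.age_max) and (np.floor(y + _EPS) >= self.year_max)
            if capped:
                if rate <= 0:
                    return np.inf
                T = s + (target - H) / rate
                return np.inf if (horizon is not None and T > horizon) else T
            step = min(np.floor(a + _EPS) + 1.0 - a, np.floor(y + _EPS) + 1.0 - y)
            if rate > 0 and H + rate * step >= target:
                T = s + (target - H) / rate
                return np.inf if (horizon is not None and T > horizon) else T
            H += rate * step
            s += step

    def sample_other_cause_times(self, ages, years, u, strata=None, horizon=None) -> np.ndarray:
        """Vectorized piecewise-exponential inversion for a whole (single
        stratum) cohort; entries whose solution exceeds ``horizon`` are inf."""
        grid = self._grids[self._key(strata)]
        ages = np.asarray(ages, dtype=float)
        years = np.broadcast_to(np.asarray(years, dtype=float), ages.shape)
        u = np.asarray(u, dtype=float)
        if np.any(u <= 0) or np.any(u >= 1):
            raise ValueError("u must lie in (0, 1)")
        target = -np.log(u)
        if horizon is None:
            horizon = (self.age_max - np.min(ages)) + 2.0
        s = np.zeros(ages.shape)
        H = np.zeros(ages.shape)
        T = np.full(ages.shape, np.inf)
        done = np.zeros(ages.shape, dtype=bool)
        while not done.all() and np.any(s[~done] < horizon):
            a = ages + s
            y = years + s
            ai, yi = self._cells(a, y)
            rate = grid[ai, yi]
            step_a = np.floor(a + _EPS) + 1.0 - a
            step_y = np.floor(y + _EPS) + 1.0 - y
            step = np.minimum(step_a, step_y)
            at_cap = (np.floor(a + _EPS) >= self.age_max) & (np.floor(y + _EPS) >= self.year_max)
            step = np.where(at_cap, np.inf, step)
            with np.errstate(invalid="ignore", divide="ignore"):
                hits = ~done & (rate > 0) & (H + rate * np.minimum(step, horizon - s) >= target)
                T = np.where(hits, s + (target - H) / rate, T)
            done |= hits
            adv = np.where(done, 0.0, np.minimum(step, horizon - s))
            H += np.where(done, 0.0, rate * adv)
            s += adv
        T[T > horizon] = np.inf
        return T

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()


def make_gompertz_lifetable(
    c0: float = -10.0,
    c1: float = 0.09,
    ages=range(0, 100),
    years=range(2005, 2021),
    sex_multipliers={"male": 1.0, "female": 0.8},
) -> LifeTable:
    """Synthetic "UK-like" life table with Gompertz-shaped rates.

    Rates are ``r(a) = m_sex * exp(c0 + c1 * a)``, constant across calendar
    years, with a female multiplier of 0.8.  This is the bundled stand-in
    for national life tables in tests and simulations.
    """
    ages = np.asarray(list(ages), dtype=int)
    years = np.asarray(list(years), dtype=int)
    rows = []
    for sex, mult in sex_multipliers.items():
        rate = mult * np.exp(c0 + c1 * ages)
        for y in years:
            rows.append(pd.DataFrame({"age": ages, "year": y, "sex": sex, "rate": rate}))
    return LifeTable(pd.concat(rows, ignore_index=True))


def read_lifetable(path, sep=",") -> LifeTable:
    """Read a long-format delimited life table (columns age, year,
    <strata...>, rate); validates grid contiguity and nonnegativity."""
    return LifeTable(pd.read_csv(path, sep=sep))


def write_lifetable(lt: LifeTable, path, sep=",") -> None:
    lt.to_frame().to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
@dataclass
class CohortData:
    """Individual-level survival records for excess hazard modelling.

    time : follow-up in years since diagnosis (nonnegative)
    status : 1 = dead, 0 = alive/censored
    covariates : (n, p) design matrix for the excess hazard model
    age : age at diagnosis in years
    year : calendar year of diagnosis
    strata : per-individual life-table stratum label (or None)
    names : covariate column names
    """

    time: np.ndarray
    status: np.ndarray
    covariates: np.ndarray
    age: np.ndarray
    year: np.ndarray
    strata: np.ndarray | None = None
    names: tuple = ()

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.status = np.asarray(self.status, dtype=int)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.shape[0] != self.time.size and self.covariates.shape[1] == self.time.size:
            self.covariates = self.covariates.T
        self.age = np.asarray(self.age, dtype=float)
        self.year = np.asarray(self.year, dtype=float)
        n = self.time.size
        if np.any(self.time < 0):
            raise ValueError("times must be nonnegative")
        if not np.isin(self.status, (0, 1)).all():
            raise ValueError("status must be 0 (alive) or 1 (dead)")
        for arr, name in ((self.status, "status"), (self.age, "age"), (self.year, "year")):
            if arr.size != n:
                raise ValueError(f"{name} has length {arr.size}, expected {n}")
        if self.covariates.shape[0] != n:
            raise ValueError("covariate matrix row count must match number of individuals")
        if self.strata is not None:
            self.strata = np.asarray(self.strata)
            if self.strata.size != n:
                raise ValueError("strata labels must match number of individuals")
        if not self.names:
            self.names = tuple(f"x{j + 1}" for j in range(self.covariates.shape[1]))
        self.names = tuple(self.names)

    @property
    def n(self) -> int:
        return int(self.time.size)

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        covariates,
        time_col="time",
        status_col="status",
        age_col="age",
        year_col="year",
        strata_col=None,
    ) -> "CohortData":
        return cls(
            time=df[time_col].to_numpy(),
            status=df[status_col].to_numpy(),
            covariates=df[list(covariates)].to_numpy(),
            age=df[age_col].to_numpy(),
            year=df[year_col].to_numpy(),
            strata=df[strata_col].to_numpy() if strata_col else None,
            names=tuple(covariates),
        )

    def to_dataframe(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"time": self.time, "status": self.status, "age": self.age, "year": self.year}
        )
        for j, name in enumerate(self.names):
            out[name] = self.covariates[:, j]
        if self.strata is not None:
            out["stratum"] = self.strata
        return out
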