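"""Scenario generators, cohort simulation, and the replication harness."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

import frailex as fx
from frailex.simulate import _draw_covariates, performance_table


def test_builtin_scenario_true_values():
    sc1 = fx.builtin_scenario("Sc1", n=100)
    assert sc1.frailty.b == 0.5
    assert (sc1.gh.baseline.sigma, sc1.gh.baseline.nu, sc1.gh.baseline.gamma) == (0.75, 1.75, 8.0)
    assert sc1.gh.alpha == sc1.gh.beta == (1.0, 1.0, 1.0, 1.0)
    far = fx.builtin_scenario("Aim2_far", n=100)
    assert far.subgroups[0].baseline.gamma == 0.75
    assert far.subgroups[1].baseline.gamma == 5.0
    assert far.sex_prob == 0.6 and far.x1_given_sex == (0.8, 0.4)
    with pytest.raises(ValueError):
        fx.builtin_scenario("Sc9", n=100)


def test_scenario_spec_invariants():
    sc1 = fx.builtin_scenario("Sc1", n=100)
    with pytest.raises(ValueError):
        replace(sc1, age_mixture=((0.5, (30, 65)), (0.3, (65, 85))))
    with pytest.raises(ValueError):
        replace(sc1, n=0)
    with pytest.raises(ValueError):
        replace(sc1, sex_prob=1.4)


def test_age_mixture_shares():
    spec = fx.builtin_scenario("Sc1", n=100_000)
    age, _, X = _draw_covariates(spec, np.random.default_rng(8))
    share_old = np.mean((age > 75) & (age < 85))
    assert share_old == pytest.approx(0.40, abs=0.01)
    assert np.mean((age > 30) & (age < 65)) == pytest.approx(0.25, abs=0.01)
    # standardized age column
    assert X[:, 0].mean() == pytest.approx(0.0, abs=1e-12)
    assert X[:, 0].std() == pytest.approx(1.0, abs=1e-12)


def test_sc1_dropout_and_total_censoring(gompertz_lt):
    """Drop-out calibrated near 5%; total censoring in the 40-45% band."""
    spec = fx.builtin_scenario("Sc1", n=5000)
    drop, cens = [], []
    for seed in range(20):
        data, latent = fx.generate_cohort(spec, gompertz_lt, seed=seed)
        drop.append((latent["cause"] == "dropout").mean())
        cens.append(1 - data.status.mean())
    assert 0.04 <= np.mean(drop) <= 0.06
    assert 0.38 <= np.mean(cens) <= 0.47


def test_admin_censored_rows_sit_exactly_at_horizon(sc1_cohort):
    _, data, latent = sc1_cohort
    admin = latent["cause"] == "admin"
    assert admin.any()
    assert np.all(data.time[admin.to_numpy()] == 5.0)
    assert data.time.max() <= 5.0
    # status flags deaths only
    dead = latent["cause"].isin(["cancer", "other"]).to_numpy()
    assert np.array_equal(data.status.astype(bool), dead)


def test_seed_determinism(gompertz_lt):
    spec = fx.builtin_scenario("Sc1", n=300)
    d1, l1 = fx.generate_cohort(spec, gompertz_lt, seed=99)
    d2, l2 = fx.generate_cohort(spec, gompertz_lt, seed=99)
    assert np.array_equal(d1.time, d2.time)
    assert np.array_equal(d1.covariates, d2.covariates)
    pd.testing.assert_frame_equal(l1, l2)
    d3, _ = fx.generate_cohort(spec, gompertz_lt, seed=100)
    assert not np.array_equal(d1.time, d3.time)


def test_zero_excess_hazard_gives_only_other_cause_deaths(gompertz_lt):
    """With the excess hazard suppressed, every death is other-cause."""
    sc1 = fx.builtin_scenario("Sc1", n=4000)
    # an enormous scale pushes every cancer event time beyond the horizon
    faint = fx.BaselineParams("pgw", 1e8, 1.75, 8.0)
    gh = fx.GHModel(faint, alpha=(0.0,) * 4, beta=(0.0,) * 4, time_index=(0, 1, 2, 3))
    spec = replace(sc1, gh=gh, age_mixture=((1.0, (70.0, 85.0)),), dropout_rate=0.0)
    data, latent = fx.generate_cohort(spec, gompertz_lt, seed=13)
    deaths = latent.loc[data.status == 1, "cause"]
    assert (deaths == "other").all()
    assert data.n_events > 0


def test_no_background_no_censoring_matches_marginal_net_survival():
    """With zero population hazard and no censoring, simulated times follow
    the gamma-frailty marginal net survival distribution (KS at 0.01)."""
    zero_lt = fx.LifeTable(
        pd.DataFrame(
            [{"age": a, "year": 2012, "rate": 0.0} for a in range(0, 100)]
        )
    )
    sc1 = fx.builtin_scenario("Sc1", n=8000)
    gh = fx.GHModel(sc1.gh.baseline, alpha=(), beta=(0.0,) * 4, time_index=())
    spec = replace(
        sc1, gh=gh, dropout_rate=0.0, admin_censor=1e6,
        sex_stratum={0: None, 1: None},
    )
    data, latent = fx.generate_cohort(spec, zero_lt, seed=21)
    assert (latent.loc[data.status == 1, "cause"] == "cancer").all()
    # the frailty marginal is heavy-tailed, so a few events outlive even this
    # horizon; compare events against the truncated marginal distribution
    assert data.status.mean() > 0.99
    b = 0.5

    def cdf(t):
        HE = fx.cum_hazard(sc1.gh.baseline, np.asarray(t, dtype=float))
        return 1 - (1 + b * HE) ** (-1 / b)

    events = data.time[data.status == 1]
    assert kstest(events, lambda t: cdf(t) / cdf(spec.admin_censor)).pvalue > 0.01


def test_performance_table_bias_identity():
    est = pd.DataFrame(
        {
            "rep": [0, 1, 2],
            "param": ["b"] * 3,
            "estimate": [0.4, 0.6, 0.8],
            "se": [0.1, 0.1, 0.1],
            "lower": [0.2, 0.4, 0.6],
            "upper": [0.6, 0.8, 1.0],
        }
    )
    table = performance_table(est, {"b": 0.5})
    row = table.loc["b"]
    assert row["bias"] == pytest.approx(row["mean_mle"] - 0.5, abs=1e-12)
    assert row["coverage"] == pytest.approx(2 / 3)
    assert 0 <= row["coverage"] <= 1


def test_run_replications_small_scale(gompertz_lt):
    spec = fx.builtin_scenario("Sc1", n=400)
    study = fx.run_replications(spec, gompertz_lt, n_reps=3, seed=7)
    assert study.n_excluded + study.estimates["rep"].nunique() == 3
    assert set(study.table.index) >= {"sigma", "nu", "gamma", "b", "beta_sex"}
    # reproducible under the same seed
    again = fx.run_replications(spec, gompertz_lt, n_reps=3, seed=7)
    pd.testing.assert_frame_equal(study.estimates, again.estimates)


def test_calibrator_hits_target(gompertz_lt):
    spec = fx.builtin_scenario("Sc1", n=100)
    rate = fx.calibrate_dropout_rate(spec, gompertz_lt, target=0.05, n_pilot=20_000, seed=3)
    _, latent = fx.generate_cohort(replace(spec, n=50_000, dropout_rate=rate), gompertz_lt, seed=4)
    assert (latent["cause"] == "dropout").mean() == pytest.approx(0.05, abs=0.01)


def test_aim2_pooled_vs_stratified(gompertz_lt):
    """Missing X1 with very different subgroup baselines: pooled subgroup
    curves are farther from the truth than stratified curves; with similar
    baselines the pooled population curve tracks the truth closely."""
    far = fx.builtin_scenario("Aim2_far", n=800)
    rep = fx.aim2_analysis(far, gompertz_lt, n_reps=6, seed=31, n_mc=40_000)
    frac = (
        (rep.deviations["pooled_dev"] > rep.deviations["strat_dev"])
        .groupby(rep.deviations["model"])
        .mean()
    )
    assert (frac >= 0.8).all()

    close = fx.builtin_scenario("Aim2_close", n=2000)
    rep2 = fx.aim2_analysis(close, gompertz_lt, n_reps=6, seed=32, n_mc=40_000)
    piv = rep2.curves.pivot_table(index="t", columns=["estimator", "scope"], values="value")
    for est in ("pooled_classical", "pooled_frailty"):
        dev = np.max(np.abs(piv[(est, "population")] - piv[("true", "population")]))
        assert dev < 0.04
    dev_strat = np.max(np.abs(piv[("strat_classical", "sex1")] - piv[("true", "sex1")]))
    assert dev_strat < 0.03
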