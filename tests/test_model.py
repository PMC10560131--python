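"""Likelihoods, maximum-likelihood fitting, Wald/MC intervals, and AIC."""

import numpy as np
import pandas as pd
import pytest

import frailex as fx
from frailex.model import ExcessHazardResults, ParamTemplate


def toy_data():
    return fx.CohortData(
        time=[0.8, 2.5, 4.0],
        status=[1, 0, 1],
        covariates=[[0.5], [-0.2], [1.0]],
        age=[70.0, 60.0, 80.0],
        year=[2012, 2012, 2012],
        names=("x1",),
    )


def test_classical_loglik_matches_hand_rolled_sum(flat_lt):
    """Independent per-observation arithmetic on a 3-row toy dataset."""
    data = toy_data()
    bp = fx.BaselineParams("pgw", 1.2, 1.5, 2.0)
    beta = np.array([0.7])
    alpha = np.array([0.3])
    psi = fx.ParamVector(bp, alpha, beta, None)
    got = fx.loglik_classical(psi, data, flat_lt, time_index=(0,))
    expected = 0.0
    for t, d, x in zip(data.time, data.status, data.covariates[:, 0]):
        eta_t = 0.3 * x
        eta_h = 0.7 * x
        ts = t * np.exp(eta_t)
        H0 = (1 + (ts / 1.2) ** 1.5) ** (1 / 2.0) - 1
        h0 = (1.5 / (2.0 * 1.2)) * (ts / 1.2) ** 0.5 * (1 + (ts / 1.2) ** 1.5) ** (1 / 2.0 - 1)
        hE = h0 * np.exp(eta_h)
        HE = H0 * np.exp(eta_h - eta_t)
        expected += d * np.log(0.02 + hE) - HE
    assert got == pytest.approx(expected, abs=1e-10)


def test_frailty_loglik_reduces_to_classical_as_b_vanishes(flat_lt, gompertz_lt):
    rng = np.random.default_rng(0)
    spec = fx.builtin_scenario("Sc1", n=250)
    for seed in (1, 2, 3):
        data, _ = fx.generate_cohort(spec, gompertz_lt, seed=seed)
        bp = fx.BaselineParams("pgw", *rng.uniform(0.5, 2.5, 3))
        alpha = rng.normal(0, 0.5, 4)
        beta = rng.normal(0, 0.5, 4)
        llf = fx.loglik_frailty(
            fx.ParamVector(bp, alpha, beta, 1e-10), data, gompertz_lt, time_index=(0, 1, 2, 3)
        )
        llc = fx.loglik_classical(
            fx.ParamVector(bp, alpha, beta, None), data, gompertz_lt, time_index=(0, 1, 2, 3)
        )
        assert llf == pytest.approx(llc, abs=1e-6)


def test_single_observation_closed_forms(flat_lt):
    bp = fx.BaselineParams("pgw", 1.0, 1.5, 2.0)
    censored = fx.CohortData(time=[2.0], status=[0], covariates=[[0.0]], age=[60.0], year=[2012])
    psi = fx.ParamVector(bp, np.zeros(0), np.zeros(1), None)
    # one censored PH individual with x=0 contributes -H0(t)
    assert fx.loglik_classical(psi, censored, flat_lt) == pytest.approx(-fx.cum_hazard(bp, 2.0))
    # one death with a negligible excess hazard contributes log hP
    dead = fx.CohortData(time=[2.0], status=[1], covariates=[[1.0]], age=[60.0], year=[2012])
    psi_small = fx.ParamVector(bp, np.zeros(0), np.array([-40.0]), None)
    assert fx.loglik_classical(psi_small, dead, flat_lt) == pytest.approx(np.log(0.02), abs=1e-6)


def test_nonfinite_parameters_are_optimizer_safe(gompertz_lt):
    spec = fx.builtin_scenario("Sc1", n=100)
    data, _ = fx.generate_cohort(spec, gompertz_lt, seed=4)
    model = fx.ExcessHazardModel(data, gompertz_lt, frailty="gamma", time_index=(0, 1, 2, 3))
    bad = np.full(model.template.k, 200.0)
    assert model._nll(bad) == pytest.approx(1e10)


def test_param_template_pack_unpack_identity():
    tpl = ParamTemplate("pgw", n_time=2, n_cov=3, has_frailty=True,
                        names=("a", "b", "c"), time_index=(0, 2))
    psi = fx.ParamVector(fx.BaselineParams("pgw", 0.75, 1.75, 8.0),
                         [0.5, -0.2], [1.0, 0.3, -0.1], 0.5)
    vec = tpl.pack(psi)
    assert vec.size == tpl.k == 9
    back = tpl.unpack(vec)
    assert back.baseline.sigma == pytest.approx(0.75, rel=1e-14)
    assert back.baseline.nu == pytest.approx(1.75, rel=1e-14)
    assert back.baseline.gamma == pytest.approx(8.0, rel=1e-14)
    assert np.allclose(back.alpha, psi.alpha) and np.allclose(back.beta, psi.beta)
    assert back.b == pytest.approx(0.5, rel=1e-14)
    assert np.allclose(tpl.pack(back), vec, rtol=1e-14, atol=1e-14)
    assert tpl.param_names == ("sigma", "nu", "gamma", "alpha_a", "alpha_c",
                               "beta_a", "beta_b", "beta_c", "b")


def test_fit_is_stationary_and_reproducible(sc1_fit):
    _, _, model, fit = sc1_fit
    assert np.max(np.abs(fit.score_tx())) < 1e-4
    refit = model.fit(init=fit.params_object)
    assert abs(refit.llf - fit.llf) < 1e-6
    assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.llf)


def test_wald_intervals_consistent_with_se(sc1_fit):
    _, _, _, fit = sc1_fit
    ci = fit.conf_int()
    est = fit.estimates_frame()
    # coefficient CIs symmetric on the natural scale
    i = list(fit.param_names).index("beta_sex")
    half = 1.959963984540054 * fit.bse[i]
    assert ci.iloc[i]["lower"] == pytest.approx(fit.params[i] - half)
    # positive-parameter CIs are log-symmetric with positive endpoints
    j = list(fit.param_names).index("b")
    assert ci.iloc[j]["lower"] > 0
    assert np.log(ci.iloc[j]["upper"] / fit.params[j]) == pytest.approx(
        np.log(fit.params[j] / ci.iloc[j]["lower"]), rel=1e-6
    )
    assert (est["lower"] <= est["estimate"]).all() and (est["estimate"] <= est["upper"]).all()


def test_parameter_recovery_classical_ph(gompertz_lt):
    """Data from a known classical PH-PGW truth: estimates within 3 SEs of
    the truth for at least 95% of parameters across seeds."""
    gh = fx.GHModel(fx.BaselineParams("pgw", 0.9, 1.4, 3.0),
                    alpha=(), beta=(0.8, 0.5, -0.3, 0.4), time_index=())
    spec = fx.ScenarioSpec(
        name="ph", n=5000, frailty=fx.FrailtySpec("none"), gh=gh,
        binary_probs={"X1": 0.5, "X2": 0.5}, dropout_rate=0.02,
    )
    truth = np.array([0.9, 1.4, 3.0, 0.8, 0.5, -0.3, 0.4])
    hits = total = 0
    for seed in range(10):
        data, _ = fx.generate_cohort(spec, gompertz_lt, seed=500 + seed)
        fit = fx.ExcessHazardModel(data, gompertz_lt, frailty=None, time_index=()).fit()
        if not fit.converged:
            continue
        tx_truth = np.concatenate([np.log(truth[:3]), truth[3:]])
        z = np.abs((fit.params_tx - tx_truth) / fit.bse_tx)
        hits += (z < 3).sum()
        total += z.size
    assert total > 0
    assert hits / total >= 0.95


def test_frailty_variance_recovered_at_scale(gompertz_lt):
    """Sc1-style truth at n=5000: the frailty fit recovers b near 0.5."""
    spec = fx.builtin_scenario("Sc1", n=5000)
    data, _ = fx.generate_cohort(spec, gompertz_lt, seed=5)
    fit = fx.ExcessHazardModel(data, gompertz_lt, frailty="gamma", time_index=(0, 1, 2, 3)).fit()
    assert fit.converged
    ci = fit.conf_int().loc["b"]
    assert 0.05 < fit.params[list(fit.param_names).index("b")] < 1.5
    assert ci["lower"] < 0.5 < ci["upper"]


def test_aic_identity_and_tie_break():
    # AIC arithmetic: loglik -100 with 12 parameters
    tpl = ParamTemplate("pgw", n_time=4, n_cov=4, has_frailty=True)
    assert 2 * tpl.k - 2 * (-100.0) == 224
    # ranking: equal loglik, fewer parameters first
    rows = pd.DataFrame({"model": ["m1", "m2"], "k": [12, 11], "loglik": [-100.0, -100.0]})
    rows["aic"] = 2 * rows["k"] - 2 * rows["loglik"]
    ranked = rows.sort_values(["aic", "k"], kind="stable")
    assert ranked.iloc[0]["k"] == 11


def test_aic_compare_requires_same_data(gompertz_lt, sc1_fit):
    spec, data, model, fit = sc1_fit
    other_data, _ = fx.generate_cohort(fx.builtin_scenario("Sc1", n=500), gompertz_lt, seed=1)
    other = fx.ExcessHazardModel(other_data, gompertz_lt, frailty=None, time_index=(0, 1, 2, 3)).fit(
        _hessian=False
    )
    with pytest.raises(ValueError):
        fx.aic_compare([fit, other])


def test_aic_prefers_frailty_under_strong_heterogeneity(gompertz_lt):
    """b = 3 truth at n = 2000: AIC should select the frailty model."""
    from dataclasses import replace

    spec = replace(fx.builtin_scenario("Sc1", n=2000), frailty=fx.FrailtySpec("gamma", 3.0))
    data, _ = fx.generate_cohort(spec, gompertz_lt, seed=12)
    mf = fx.ExcessHazardModel(data, gompertz_lt, frailty="gamma", time_index=(0, 1, 2, 3)).fit()
    mc = fx.ExcessHazardModel(data, gompertz_lt, frailty=None, time_index=(0, 1, 2, 3)).fit()
    ranking = fx.aic_compare([mf, mc])
    assert ranking.iloc[0]["model"].startswith("frailty")
    assert set(ranking["rank"]) == {1, 2}


def test_mc_ci_degenerate_covariance_gives_point_curve(sc1_fit):
    _, _, _, fit = sc1_fit
    saved = fit.cov_tx
    try:
        fit.cov_tx = np.zeros_like(saved)
        tab = fit.mc_ci_net_survival(n_draws=50, seed=0)
        assert np.allclose(tab["lower"], tab["estimate"], atol=1e-12)
        assert np.allclose(tab["upper"], tab["estimate"], atol=1e-12)
    finally:
        fit.cov_tx = saved


def test_mc_ci_contains_point_estimate(sc1_fit):
    _, _, _, fit = sc1_fit
    tab = fit.mc_ci_net_survival(n_draws=200, seed=3)
    assert (tab["lower"] <= tab["estimate"] + 1e-12).all()
    assert (tab["upper"] >= tab["estimate"] - 1e-12).all()
    tab2 = fit.mc_ci_net_survival(n_draws=200, seed=3)
    assert np.allclose(tab["lower"], tab2["lower"])  # seeded reproducibility


def test_mc_ci_width_shrinks_with_sample_size(gompertz_lt):
    """Pointwise interval width scales roughly as 1/sqrt(n)."""
    widths = {}
    for n in (500, 8000):
        spec = fx.builtin_scenario("Sc1", n=n)
        data, _ = fx.generate_cohort(spec, gompertz_lt, seed=9)
        fit = fx.ExcessHazardModel(data, gompertz_lt, frailty=None, time_index=(0, 1, 2, 3)).fit()
        assert fit.converged
        tab = fit.mc_ci_net_survival(n_draws=400, seed=1)
        mid = tab.iloc[np.searchsorted(tab["t"].to_numpy(), 2.5)]
        widths[n] = mid["upper"] - mid["lower"]
    ratio = widths[500] / widths[8000]
    assert 2.0 < ratio < 8.0  # 4x expected for a 16x sample-size increase


def test_results_serialization_round_trip(tmp_path, sc1_fit):
    _, data, _, fit = sc1_fit
    path = tmp_path / "fit.json"
    fit.save(path)
    loaded = ExcessHazardResults.load(path)
    assert loaded.aic == pytest.approx(fit.aic)
    assert np.allclose(loaded.params, fit.params)
    curve = loaded.net_survival(X=data.covariates)
    assert np.allclose(curve.values, fit.net_survival().values)


def test_model_requires_events_and_strata(gompertz_lt):
    no_events = fx.CohortData(time=[1.0], status=[0], covariates=[[0.0]], age=[60], year=[2012])
    with pytest.raises(ValueError):
        fx.ExcessHazardModel(no_events, gompertz_lt, frailty=None, time_index=())
    some = fx.CohortData(time=[1.0], status=[1], covariates=[[0.0]], age=[60], year=[2012])
    with pytest.raises(ValueError):
        # stratified table but no strata labels on the cohort
        fx.ExcessHazardModel(some, gompertz_lt, frailty=None, time_index=())
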