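"""Mixed-model engine: oracles, contracts, parameter recovery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import optimize, special

from coucal import mixed, synth


def agh_loglik_poisson(y, X, g, beta, sd, nodes=21):
    """Adaptive Gauss-Hermite marginal log-likelihood (independent oracle).

    Each group's 1-D integral is centred at its conditional mode and scaled
    by the curvature there, then evaluated on 21 probabilists' Hermite
    nodes.
    """
    zn, wts = np.polynomial.hermite_e.hermegauss(nodes)
    ll = 0.0
    for j in np.unique(g):
        m = g == j
        etaj = X[m] @ beta

        def h(b):
            e = etaj + b
            return float(np.sum(y[m] * e - np.exp(e) - special.gammaln(y[m] + 1)) - 0.5 * b**2 / sd**2)

        bhat = optimize.minimize_scalar(
            lambda b: -h(b), bounds=(-15, 15), method="bounded", options={"xatol": 1e-12}
        ).x
        s = 1.0 / np.sqrt(np.sum(np.exp(etaj + bhat)) + 1.0 / sd**2)
        vals = np.array([h(bhat + s * z) + 0.5 * z**2 for z in zn])
        ll += special.logsumexp(vals + np.log(wts)) + np.log(s) - 0.5 * np.log(2 * np.pi) - np.log(sd)
    return ll


def test_laplace_matches_adaptive_quadrature():
    """On well-informed single-factor problems (8 groups x 200 obs) the
    Laplace marginal log-likelihood agrees with adaptive GH-21 to 1e-4."""
    rng = np.random.default_rng(5)
    g = np.repeat(np.arange(8), 400)
    x = rng.normal(size=len(g))
    y = rng.poisson(np.exp(4.0 + 0.3 * x + rng.normal(0, 0.25, 8)[g]))
    X = np.column_stack([np.ones(len(g)), x])
    beta = np.array([4.0, 0.3])
    lap = mixed.laplace_loglik(y, X, [g], "poisson", beta, [0.25])
    agh = agh_loglik_poisson(y, X, g, beta, 0.25)
    assert abs(lap - agh) < 1e-4


def test_zero_variance_poisson_equals_glm():
    rng = np.random.default_rng(11)
    g = np.repeat(np.arange(10), 20)
    x = rng.normal(size=len(g))
    off = np.log(rng.uniform(30, 200, len(g)))
    y = rng.poisson(np.exp(-2.0 + 0.3 * x + off))
    X = np.column_stack([np.ones(len(g)), x])
    fit = mixed.fit_glmm(y, X, [g], "poisson", offset=off, fix_sd={"group0": 0.0})
    glm = sm.GLM(y, X, family=sm.families.Poisson(), offset=off).fit()
    assert np.abs(fit.params - glm.params).max() < 1e-6


def test_zero_variance_binomial_equals_irls():
    rng = np.random.default_rng(13)
    g = np.repeat(np.arange(10), 30)
    x = rng.normal(size=len(g))
    y = (rng.random(len(g)) < special.expit(0.5 + 0.8 * x)).astype(float)
    X = np.column_stack([np.ones(len(g)), x])
    fit = mixed.fit_glmm(y, X, [g], "binomial", fix_sd={"group0": 0.0})
    glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    assert np.abs(fit.params - glm.params).max() < 1e-6


def test_offset_contract_exact_shift(focal_obs):
    """Doubling every watch duration shifts only the intercept, by -log 2."""
    fit1 = mixed.fit_poisson_glmm(focal_obs)
    doubled = focal_obs.copy()
    doubled["duration_min"] *= 2.0
    doubled["perch_min"] *= 2.0
    fit2 = mixed.fit_poisson_glmm(doubled)
    diff = fit1.params - fit2.params
    assert diff[0] == pytest.approx(np.log(2), abs=1e-6)
    assert np.abs(diff[1:]).max() < 1e-6


def test_single_nest_raises():
    checks = pd.DataFrame(
        {"nest_id": ["n1"] * 20, "time_of_day": np.linspace(7, 17, 20), "sex_incubating": ["male"] * 20}
    )
    with pytest.raises(ValueError):
        mixed.fit_binomial_glmm(checks)


def test_binomial_recovery_no_nest_variance():
    """sd_nest = 0 truth, p = 0.8, 2000 checks: intercept near logit(0.8)."""
    checks = synth.simulate_incubation_checks(special.logit(0.8), 0.0, 0.0, 100, 20, seed=21)
    fit = mixed.fit_binomial_glmm(checks)
    p = 0.8
    se = np.sqrt(1.0 / (2000 * p * (1 - p)))  # binomial information at truth
    assert abs(fit.params[0] - special.logit(0.8)) < 4 * se
    assert fit.re_sd["nest"] < 0.2


def test_all_zero_stratum_dropped_with_warning(focal_obs):
    with pytest.warns(UserWarning, match="zero"):
        fit = mixed.fit_poisson_glmm(focal_obs)
    assert fit.flags["dropped_zero_strata"] == [["black", "female"]]


def test_lmm_degenerate_nesting_equals_ols():
    """One observation per nest: the LMM collapses to ordinary least squares."""
    rng = np.random.default_rng(17)
    n = 40
    daily = pd.DataFrame(
        {
            "nest_id": [f"n{i}" for i in range(n)],
            "species": ["black"] * (n // 2) + ["white-browed"] * (n // 2),
            "n_bouts": rng.normal(5, 1.5, n).round(),
        }
    )
    daily.loc[daily["species"] == "white-browed", "n_bouts"] -= 3
    fit = mixed.fit_lmm(daily, response="n_bouts")
    X = np.column_stack([np.ones(n), (daily["species"] == "white-browed").to_numpy(float)])
    ols = np.linalg.lstsq(X, daily["n_bouts"].to_numpy(float), rcond=None)[0]
    assert np.abs(fit.params - ols).max() < 1e-6


def test_lmm_cross_check_against_statsmodels():
    """REML estimates agree with statsmodels MixedLM on nested data."""
    rng = np.random.default_rng(23)
    nests = np.repeat(np.arange(20), 4)
    species = np.where(nests < 10, "black", "white-browed")
    y = 6.0 - 3.0 * (nests >= 10) + rng.normal(0, 1.2, 20)[nests] + rng.normal(0, 1.0, 80)
    daily = pd.DataFrame({"nest_id": [f"n{j}" for j in nests], "species": species, "n_bouts": y})
    fit = mixed.fit_lmm(daily, response="n_bouts")
    X = np.column_stack([np.ones(80), (species == "white-browed").astype(float)])
    sm_fit = sm.MixedLM(y, X, groups=nests).fit(reml=True)
    assert np.abs(fit.params - sm_fit.fe_params).max() < 1e-4
    assert fit.re_sd["nest"] == pytest.approx(np.sqrt(np.asarray(sm_fit.cov_re)[0, 0]), abs=1e-3)
    assert fit.resid_sd == pytest.approx(np.sqrt(sm_fit.scale), abs=1e-3)


def test_lmm_species_contrast_sign_at_field_scale():
    """black 6 vs white-browed 2 bouts/day: contrast negative every time."""
    rng = np.random.default_rng(29)
    signs = []
    for rep in range(20):
        rows = []
        for sp, lam, n_nests in (("black", 6.0, 10), ("white-browed", 2.0, 11)):
            for j in range(n_nests):
                nest_eff = rng.normal(0, 0.5)
                for d in range(4):
                    rows.append(
                        {"nest_id": f"{sp}{j}", "species": sp, "n_bouts": rng.poisson(max(lam + nest_eff, 0.1))}
                    )
        fit = mixed.fit_lmm(pd.DataFrame(rows), response="n_bouts")
        signs.append(fit.params[1] < 0)
    assert all(signs)


def test_offtime_trivial_half_proportion(focal_obs):
    obs = focal_obs.copy()
    obs["perch_min"] = obs["duration_min"] / 2.0
    fit = mixed.fit_offtime_model(obs)
    assert fit.params[0] == pytest.approx(0.5, abs=1e-6)
    assert np.abs(fit.params[1:]).max() < 1e-6


def test_offtime_interaction_sign_recovery():
    """White-browed 0.25 vs male black 0.10 perched: interaction recovered
    with the right sign (the two wb sexes equal, so the interaction must
    cancel the main sex effect)."""
    truth = synth.FeedingTruth()
    design = synth.ObservationDesign(n_nests={"black": 30, "white-browed": 25})
    ok = 0
    for rep in range(10):
        obs = synth.simulate_focal_observations(truth, design, seed=400 + rep)
        obs = obs[~((obs.species == "black") & (obs.sex == "female"))]
        fit = mixed.fit_offtime_model(obs)
        est = dict(zip(fit.param_names, fit.params))
        ok += est["species_wb"] > 0
    assert ok >= 9


def test_offtime_time_slope_sign(focal_obs):
    fit = mixed.fit_offtime_model(focal_obs)
    est = dict(zip(fit.param_names, fit.params))
    assert est["time_z"] < 0  # off-times decrease over the day


def test_perch_exceeding_duration_rejected(focal_obs):
    obs = focal_obs.copy()
    obs.loc[obs.index[0], "perch_min"] = obs.loc[obs.index[0], "duration_min"] + 1
    with pytest.raises(ValueError):
        mixed.fit_offtime_model(obs)


def test_posterior_sim_properties(focal_obs):
    fit = mixed.fit_poisson_glmm(focal_obs)
    mixed.posterior_sim(fit, n_draws=4000, seed=9)
    for nm, est in zip(fit.param_names, fit.params):
        lo, hi = fit.cri[nm]
        assert lo <= est <= hi
    cri1 = dict(fit.cri)
    mixed.posterior_sim(fit, n_draws=4000, seed=9)
    assert cri1 == fit.cri  # seeded determinism


def test_cri_width_scales_inverse_sqrt_n():
    rng = np.random.default_rng(33)

    def width(n_nests):
        checks = synth.simulate_incubation_checks(0.8, 0.3, 0.4, n_nests, 8, seed=55)
        fit = mixed.fit_binomial_glmm(checks)
        mixed.posterior_sim(fit, n_draws=4000, seed=3)
        lo, hi = fit.cri["intercept"]
        return hi - lo

    w1, w4 = width(25), width(100)
    assert w4 < w1 * 0.75  # shrinks roughly like 1/sqrt(n)


def test_r_squared_closed_form_gaussian():
    r2m, r2c = mixed.r_squared_components(1.0, 1.0, 2.0)
    assert r2m == pytest.approx(0.25)
    assert r2c == pytest.approx(0.50)


def test_r_squared_zero_slopes():
    """No fixed slopes but real nest variance: marginal ~ 0 < conditional."""
    checks = synth.simulate_incubation_checks(0.0, 0.0, 1.5, 60, 10, seed=61)
    fit = mixed.fit_binomial_glmm(checks)
    r2m, r2c = mixed.r_squared(fit)
    assert r2m < 0.05
    assert r2c > r2m
    assert 0 <= r2m <= r2c <= 1


def test_conditional_at_least_marginal(focal_obs):
    for fit in (
        mixed.fit_poisson_glmm(focal_obs),
        mixed.fit_offtime_model(focal_obs),
    ):
        r2m, r2c = mixed.r_squared(fit)
        assert 0 <= r2m <= r2c <= 1
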