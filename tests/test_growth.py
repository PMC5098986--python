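"""Growth model: closed forms, nonlinear-LS oracle, recovery, CIs."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import curve_fit

from coucal import synth
from coucal.datasets import ADULT_MASS_G, GROWTH_PARAMS
from coucal.growth import (
    fit_logistic_growth,
    predict_mass,
    re_correlations,
    relative_fledging_mass,
)


def logistic(t, A, K, I):
    return A / (1 + np.exp(-K * (t - I)))


def test_predict_mass_inflection_and_degenerate():
    assert predict_mass(77.1, 0.377, 6.2, 6.2) == pytest.approx(38.55)
    assert predict_mass(100.0, 0.0, 6.0, -50.0) == pytest.approx(50.0)  # K=0: flat at A/2
    assert predict_mass(100.0, 0.0, 6.0, 50.0) == pytest.approx(50.0)
    t = np.arange(0, 20)
    m = predict_mass(90.0, 0.4, 6.0, t)
    assert (np.diff(m) > 0).all()
    assert predict_mass(90.0, 0.4, 6.0, 1e4) == pytest.approx(90.0)


@pytest.mark.parametrize(
    "A,adult,expect",
    [(77.1, 165.9, 46.5), (66.9, 98.0, 68.3), (97.2, 153.8, 63.2), (93.5, 136.1, 68.7), (80.0, 80.0, 100.0)],
)
def test_relative_fledging_mass(A, adult, expect):
    assert relative_fledging_mass(A, adult) == expect


def test_relative_fledging_table_consistent():
    from coucal.datasets import relative_fledging_table

    table = relative_fledging_table()
    for key, pct in table.items():
        assert pct == relative_fledging_mass(GROWTH_PARAMS[key]["A"], ADULT_MASS_G[key])


def test_zero_noise_matches_nonlinear_ls_oracle():
    """No random effects, tiny residual: the mixed fitter's fixed effects
    agree with an independent nonlinear least-squares fit (curve_fit)."""
    rng = np.random.default_rng(3)
    truth = synth.GrowthTruth(
        A=77.1, K=0.377, I=6.2,
        sd_A_nest=0, sd_I_nest=0, corr_AI_nest=0,
        sd_A_nestling=0, sd_I_nestling=0, corr_AI_nestling=0,
        resid_sd=0.5, n_nests=20, nestlings_per_nest=2,
    )
    df = synth.simulate_growth_data(truth, seed=5)
    fit = fit_logistic_growth(df)
    popt, _ = curve_fit(
        logistic, df["age_d"], df["mass_g"], p0=(90.0, 0.4, 6.0), maxfev=10000
    )
    got = np.array([fit.params["A"], fit.params["K"], fit.params["I"]])
    assert np.allclose(got, popt, rtol=2e-3)
    # and both sit on the truth
    assert np.allclose(got, [77.1, 0.377, 6.2], rtol=0.02)


def test_exact_recovery_noiseless():
    truth = synth.GrowthTruth(
        A=97.2, K=0.369, I=6.3,
        sd_A_nest=0, sd_I_nest=0, corr_AI_nest=0,
        sd_A_nestling=0, sd_I_nestling=0, corr_AI_nestling=0,
        resid_sd=0.0, n_nests=10, nestlings_per_nest=2,
    )
    df = synth.simulate_growth_data(truth, seed=6)
    fit = fit_logistic_growth(df)
    assert fit.params["A"] == pytest.approx(97.2, rel=1e-5)
    assert fit.params["K"] == pytest.approx(0.369, rel=1e-4)
    assert fit.params["I"] == pytest.approx(6.3, rel=1e-4)


def test_single_replicate_recovery_with_random_effects(growth_data):
    """Field-scale heterogeneity (60 nests): estimates land near the truth
    and the Wald CIs cover it."""
    truth, df = growth_data
    fit = fit_logistic_growth(df)
    assert fit.converged and fit.hessian_pd
    assert abs(fit.params["A"] - truth.A) / truth.A < 0.05
    assert abs(fit.params["K"] - truth.K) / truth.K < 0.08
    assert abs(fit.params["I"] - truth.I) / truth.I < 0.08
    for nm, true_val in (("A", truth.A), ("K", truth.K), ("I", truth.I)):
        lo, hi = fit.ci[nm]
        assert lo < fit.params[nm] < hi
    # variance components in the right neighbourhood
    assert abs(fit.ranef["nest"]["sd_A"] - truth.sd_A_nest) < 4.0
    assert abs(fit.resid_sd - truth.resid_sd) < 1.0


def test_start_robustness(growth_data):
    """Different sensible starting values reach the same optimum; the field
    convention (A0 = mean pre-fledging mass) is one of them."""
    _, df = growth_data
    fit_default = fit_logistic_growth(df)
    fit_alt = fit_logistic_growth(df, start=(92.4, 0.3, 5.0))
    for nm in ("A", "K", "I"):
        assert fit_default.params[nm] == pytest.approx(fit_alt.params[nm], rel=1e-3)


def test_re_correlations_table(growth_data):
    truth, df = growth_data
    fit = fit_logistic_growth(df)
    tab = re_correlations(fit)
    assert list(tab["level"]) == ["nest", "nestling"]
    assert (tab["corr"].abs() <= 1).all()
    nest_row = tab[tab["level"] == "nest"].iloc[0]
    # generating nest-level correlation is 0.8: the CI should exclude zero
    assert nest_row["meaningful"]
    assert nest_row["corr"] > 0.3


def test_tarsus_same_code_path(growth_data):
    """A tarsus response runs through the identical machinery."""
    _, df = growth_data
    df = df.copy()
    df["tarsus_mm"] = df["mass_g"] * 0.35 + 5.0  # affine proxy, same structure
    fit = fit_logistic_growth(df, response="tarsus")
    assert fit.response == "tarsus"
    assert fit.converged


def test_age_cap_excludes_late_measurements(growth_data):
    _, df = growth_data
    extra = df.head(10).copy()
    extra["age_d"] = 25.0
    extra["mass_g"] = 40.0  # post-fledging drop that would bias A
    fit_capped = fit_logistic_growth(pd.concat([df, extra]), age_cap=16.0)
    fit_plain = fit_logistic_growth(df)
    assert fit_capped.params["A"] == pytest.approx(fit_plain.params["A"], rel=1e-6)


def test_too_few_nests_rejected():
    truth = synth.GrowthTruth(n_nests=3)
    df = synth.simulate_growth_data(truth, seed=9)
    with pytest.raises(ValueError, match="nests"):
        fit_logistic_growth(df)


def test_nestling_switching_nests_rejected(growth_data):
    _, df = growth_data
    df = df.copy()
    df.loc[df.index[-1], "nest_id"] = df["nest_id"].iloc[0]
    with pytest.raises(ValueError, match="more than one nest"):
        fit_logistic_growth(df)
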