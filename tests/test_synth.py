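"""Synthetic-data generators: determinism, closed forms, Monte-Carlo checks."""

import numpy as np
import pandas as pd
import pytest

from coucal import synth
from coucal.bouts import detect_absence_bouts


def test_fixed_seed_bitwise_identical():
    for maker in (
        lambda s: synth.simulate_temperature_trace(synth.IncubationSchedule(), 2, seed=s)[0],
        lambda s: synth.simulate_incubation_checks(0.5, 0.2, 0.5, 10, 5, seed=s),
        lambda s: synth.simulate_focal_observations(
            synth.FeedingTruth(), synth.ObservationDesign(n_nests={"black": 5, "white-browed": 5}), seed=s
        ),
        lambda s: synth.simulate_growth_data(synth.GrowthTruth(n_nests=8), seed=s),
    ):
        a, b = maker(123), maker(123)
        pd.testing.assert_frame_equal(a, b)


def test_quantization_multiples():
    for q in (0.5, 0.25):
        sched = synth.IncubationSchedule(quantization=q)
        trace, _ = synth.simulate_temperature_trace(sched, 1, seed=4)
        ratio = trace["temp_c"].to_numpy() / q
        assert np.allclose(ratio, np.round(ratio), atol=1e-9)


def test_no_event_trace_is_flat():
    sched = synth.IncubationSchedule(bouts_per_day=0.0, noise_sd=0.0)
    trace, truth = synth.simulate_temperature_trace(sched, 2, seed=8)
    assert truth.empty
    assert (trace["temp_c"] == 34.0).all()


def test_square_wave_single_bout_round_trip():
    """One 30-min bout, instant relaxation: the trace is a hand-computable
    square wave, and the detector returns exactly the truth."""
    sched = synth.square_wave_schedule(bouts_per_day=1.0, bout_mean_min=30.0, bout_sd_min=0.0)
    for seed in range(10):
        trace, truth = synth.simulate_temperature_trace(sched, 1, seed=seed)
        if len(truth) != 1:
            continue
        assert truth["duration_min"].iloc[0] == pytest.approx(30.0)
        # trace is exactly two levels
        assert set(np.round(trace["temp_c"].unique(), 6)) <= {34.0, 25.0}
        bouts = detect_absence_bouts(trace)
        assert len(bouts) == 1
        assert bouts[0].start == truth["start"].iloc[0]
        assert bouts[0].end == truth["end"].iloc[0]
        break
    else:
        pytest.fail("no single-bout realization found")


def test_infeasible_schedule_rejected():
    with pytest.raises(ValueError, match="infeasible"):
        synth.simulate_temperature_trace(
            synth.IncubationSchedule(bouts_per_day=100.0, bout_mean_min=30.0), 1, seed=0
        )


def test_poisson_rate_recovery_law_of_large_numbers():
    """No heterogeneity, no slopes: empirical visits/min converges to the
    generating rate (10^4 observations)."""
    rate = 3.8 / 60.0
    truth = synth.FeedingTruth(
        log_rates={("black", "male"): np.log(rate), ("black", "female"): -np.inf,
                   ("white-browed", "male"): np.log(rate), ("white-browed", "female"): np.log(rate)},
        brood_mass_slope=0.0, time_slope=0.0, sd_parent=0.0, sd_nest=0.0,
    )
    design = synth.ObservationDesign(n_nests={"black": 900, "white-browed": 900}, obs_per_parent=(3, 5))
    obs = synth.simulate_focal_observations(truth, design, seed=17)
    obs = obs[~((obs["species"] == "black") & (obs["sex"] == "female"))]
    assert len(obs) >= 10_000
    emp = obs["feeding_visits"].sum() / obs["duration_min"].sum()
    se = np.sqrt(rate / obs["duration_min"].sum())
    assert abs(emp - rate) < 4 * se


def test_poisson_variance_to_mean_unity():
    """At fixed covariates with zero random-effect SDs the counts are
    plain Poisson: variance/mean of standardized counts ~ 1."""
    truth = synth.FeedingTruth(brood_mass_slope=0.0, time_slope=0.0, sd_parent=0.0, sd_nest=0.0)
    design = synth.ObservationDesign(n_nests={"black": 500, "white-browed": 1}, obs_per_parent=(3, 4))
    obs = synth.simulate_focal_observations(truth, design, seed=19)
    obs = obs[(obs["species"] == "black") & (obs["sex"] == "male")]
    mu = obs["duration_min"] * np.exp(list(truth.log_rates.values())[0])
    z = (obs["feeding_visits"] - mu) / np.sqrt(mu)
    assert np.var(z) == pytest.approx(1.0, abs=0.15)


def test_zero_rate_stratum_all_zero():
    obs = synth.simulate_focal_observations(
        synth.FeedingTruth(), synth.ObservationDesign(n_nests={"black": 40, "white-browed": 5}), seed=23
    )
    bf = obs[(obs["species"] == "black") & (obs["sex"] == "female")]
    assert len(bf) > 0
    assert (bf["feeding_visits"] == 0).all()


def test_invalid_duration_design_rejected():
    with pytest.raises(ValueError):
        synth.ObservationDesign(duration_range=(0.0, 100.0))
    with pytest.raises(ValueError):
        synth.ObservationDesign(duration_range=(-5.0, 100.0))


def test_growth_inflection_closed_form():
    """Zero noise at the inflection point: mass is exactly A/2 = 38.55 g for
    the female black coucal curve (A=77.1, K=0.377, I=6.2)."""
    truth = synth.GrowthTruth(
        A=77.1, K=0.377, I=6.2,
        sd_A_nest=0, sd_I_nest=0, corr_AI_nest=0,
        sd_A_nestling=0, sd_I_nestling=0, corr_AI_nestling=0,
        resid_sd=0, n_nests=5, nestlings_per_nest=1, ages=(6.2,),
    )
    df = synth.simulate_growth_data(truth, seed=1)
    assert np.allclose(df["mass_g"], 38.55)


def test_growth_asymptote():
    truth = synth.GrowthTruth(
        sd_A_nest=0, sd_I_nest=0, corr_AI_nest=0,
        sd_A_nestling=0, sd_I_nestling=0, corr_AI_nestling=0,
        resid_sd=0, n_nests=2, nestlings_per_nest=1, ages=(200.0,),
    )
    df = synth.simulate_growth_data(truth, seed=1)
    assert np.allclose(df["mass_g"], truth.A, rtol=1e-9)


def test_growth_deterministic_curve_machine_precision():
    truth = synth.GrowthTruth(
        sd_A_nest=0, sd_I_nest=0, corr_AI_nest=0,
        sd_A_nestling=0, sd_I_nestling=0, corr_AI_nestling=0,
        resid_sd=0, n_nests=3, nestlings_per_nest=2,
    )
    df = synth.simulate_growth_data(truth, seed=2)
    expect = truth.A / (1 + np.exp(-truth.K * (df["age_d"] - truth.I)))
    assert np.allclose(df["mass_g"], expect, rtol=0, atol=1e-12)


def test_growth_truncation_flagged():
    truth = synth.GrowthTruth(resid_sd=30.0, n_nests=40, ages=(1.0,))
    df = synth.simulate_growth_data(truth, seed=3)
    assert df["truncated"].any()
    assert (df.loc[df["truncated"], "mass_g"] == 0.1).all()
    assert (df["mass_g"] >= 0.1).all()


def test_growth_invalid_correlation_rejected():
    with pytest.raises(ValueError):
        synth.GrowthTruth(corr_AI_nest=1.5)


def test_incubation_fraction_converges():
    from scipy.special import expit, logit

    checks = synth.simulate_incubation_checks(logit(0.809), 0.0, 0.0, 200, 25, seed=29)
    frac = (checks["sex_incubating"] == "male").mean()
    se = np.sqrt(0.809 * 0.191 / len(checks))
    assert abs(frac - 0.809) < 4 * se


def test_incubation_balanced_and_empty_cases():
    checks = synth.simulate_incubation_checks(0.0, 0.0, 0.0, 150, 20, seed=31)
    assert abs((checks["sex_incubating"] == "male").mean() - 0.5) < 0.02
    empty = synth.simulate_incubation_checks(0.0, 0.0, 0.0, 5, 0, seed=31)
    assert empty.empty


def test_prey_counts_multinomial():
    props = {"grasshoppers": 0.73, "frogs": 0.14, "mantises": 0.13}
    totals = np.zeros(3)
    reps = 40
    for s in range(reps):
        c = synth.simulate_prey_counts(props, 673, seed=1000 + s)
        totals += [c["grasshoppers"], c["frogs"], c["mantises"]]
    means = totals / reps
    for m, p in zip(means, props.values()):
        se = np.sqrt(673 * p * (1 - p) / reps)
        assert abs(m - 673 * p) < 4 * se


def test_prey_counts_validation():
    with pytest.raises(ValueError):
        synth.simulate_prey_counts({"a": 0.6, "b": 0.6}, 10, seed=0)
    zeros = synth.simulate_prey_counts({"a": 0.5, "b": 0.5}, 0, seed=0)
    assert zeros == {"a": 0, "b": 0}
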