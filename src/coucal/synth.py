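"""Synthetic field data with known ground truth.

Generators for the five input streams the analyses consume: nest-temperature
logger traces, incubation-identity checks, nest focal observations (feeding
visits and perch time), repeated nestling measurements, and prey tallies.
Each generator returns both the data and the generating truth so downstream
estimators have a parameter-recovery oracle.  All randomness flows through a
single integer seed; a fixed seed gives bit-identical output.

The temperature generator uses first-order exponential relaxation of the
logger reading toward the ambient temperature while the incubating bird is
off the nest and toward a steady incubation level while it sits, with
separate cooling and warming time constants — the simplest dynamics that
reproduces the characteristic drop/recover shape of real off-bouts.  Night
time (outside the diurnal window) is always "on nest".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from coucal.datasets import BLACK, GROWTH_PARAMS, GROWTH_RANEF, WHITE_BROWED

# --------------------------------------------------------------------------
# incubation / temperature traces
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class IncubationSchedule:
    """Ground truth for one nest's diurnal incubation rhythm.

    ``day_start``/``day_end`` are clock minutes since midnight; absence bouts
    are only generated inside this window.  ``tau_cool``/``tau_warm`` are the
    exponential time constants (minutes) of the logger reading while the bird
    is off / on the nest.  Readings are noise-added then quantized to
    ``quantization`` degC steps, emulating a 0.5 degC logger sampling every
    3 minutes.
    """

    day_start: float = 6 * 60.0
    day_end: float = 19.5 * 60.0
    bouts_per_day: float = 6.0
    bout_mean_min: float = 18.0
    bout_sd_min: float = 8.0
    on_temp: float = 34.0
    ambient_mean: float = 25.0
    ambient_amp: float = 4.0
    ambient_peak_hour: float = 14.0
    tau_cool: float = 8.0
    tau_warm: float = 5.0
    noise_sd: float = 0.25
    quantization: float = 0.5
    cadence_min: float = 3.0

    def __post_init__(self) -> None:
        if not (0 <= self.day_start < self.day_end <= 24 * 60):
            raise ValueError("day window must lie inside [00:00, 24:00)")
        if self.tau_cool <= 0 or self.tau_warm <= 0:
            raise ValueError("relaxation time constants must be positive")
        if self.bout_mean_min <= 0:
            raise ValueError("bout durations must be positive")
        if self.quantization <= 0:
            raise ValueError("quantization step must be positive")
        if (24 * 60) % self.cadence_min:
            raise ValueError("cadence must divide 24 h")

    def ambient(self, clock_min: np.ndarray) -> np.ndarray:
        """Diel sinusoid of ambient temperature at clock time (minutes)."""
        phase = 2 * np.pi * (clock_min / 60.0 - self.ambient_peak_hour) / 24.0
        return self.ambient_mean + self.ambient_amp * np.cos(phase)


def simulate_temperature_trace(
    schedule: IncubationSchedule,
    n_days: int,
    seed: int,
    nest_id: str = "nest-1",
    start_date: str = "2006-02-01",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one nest's logger trace plus the true off-bout list.

    Returns ``(trace, truth)``: *trace* has columns ``nest_id, timestamp,
    temp_c`` at the schedule's cadence; *truth* has one row per off-bout
    (``start, end, duration_min``), snapped to the sampling grid, with
    overlapping generated bouts merged.  The parent is off the nest during
    samples ``[start, end)`` and back on the nest at ``end``.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    window = schedule.day_end - schedule.day_start
    if schedule.bouts_per_day * schedule.bout_mean_min > window:
        raise ValueError("infeasible schedule: expected bout time exceeds day window")

    rng = np.random.default_rng(seed)
    dt = schedule.cadence_min
    per_day = int(round(24 * 60 / dt))
    n = n_days * per_day
    clock = (np.arange(n) * dt) % (24 * 60)

    # draw bouts day by day, snap to grid, merge overlaps
    intervals: list[tuple[int, int]] = []
    for day in range(n_days):
        k = rng.poisson(schedule.bouts_per_day)
        for _ in range(k):
            dur = rng.normal(schedule.bout_mean_min, schedule.bout_sd_min)
            dur = max(dur, dt)
            start = rng.uniform(schedule.day_start, schedule.day_end - dur)
            s = day * per_day + int(round(start / dt))
            e = s + max(1, int(round(dur / dt)))
            e = min(e, day * per_day + int(round(schedule.day_end / dt)))
            if e > s:
                intervals.append((s, e))
    intervals.sort()
    merged: list[list[int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    off = np.zeros(n, dtype=bool)
    for s, e in merged:
        off[s:e] = True

    # exponential relaxation toward the state-dependent target
    target = np.where(off, schedule.ambient(clock), schedule.on_temp)
    decay_cool = math.exp(-dt / schedule.tau_cool)
    decay_warm = math.exp(-dt / schedule.tau_warm)
    temp = np.empty(n)
    temp[0] = schedule.on_temp
    for i in range(1, n):
        decay = decay_cool if off[i] else decay_warm
        temp[i] = target[i] + (temp[i - 1] - target[i]) * decay

    if schedule.noise_sd > 0:
        temp = temp + rng.normal(0.0, schedule.noise_sd, n)
    q = schedule.quantization
    temp = np.round(temp / q) * q

    t0 = pd.Timestamp(start_date)
    stamps = t0 + pd.to_timedelta(np.arange(n) * dt, unit="m")
    trace = pd.DataFrame({"nest_id": nest_id, "timestamp": stamps, "temp_c": temp})
    truth = pd.DataFrame(
        {
            "nest_id": nest_id,
            "start": [stamps[s] for s, _ in merged],
            "end": [stamps[e] if e < n else stamps[n - 1] + pd.Timedelta(minutes=dt) for _, e in merged],
            "duration_min": [(e - s) * dt for s, e in merged],
        }
    )
    return trace, truth


# --------------------------------------------------------------------------
# incubation-identity checks
# --------------------------------------------------------------------------


def simulate_incubation_checks(
    intercept: float,
    time_slope: float,
    sd_nest: float,
    n_nests: int,
    checks_per_nest: int,
    seed: int,
) -> pd.DataFrame:
    """Bernoulli draws of which sex is found incubating at a nest check.

    ``P(male) = logit^-1(intercept + time_slope * z_time + nest_effect)``
    where ``z_time`` is the standardized clock time of the check (checks are
    drawn uniformly over 07:00-17:00, the diurnal checking window) and nest
    effects are iid ``N(0, sd_nest^2)``.
    """
    if sd_nest < 0:
        raise ValueError("sd_nest must be >= 0")
    if n_nests < 1 or checks_per_nest < 0:
        raise ValueError("need n_nests >= 1 and checks_per_nest >= 0")
    rng = np.random.default_rng(seed)
    rows = n_nests * checks_per_nest
    if rows == 0:
        return pd.DataFrame(columns=["nest_id", "time_of_day", "sex_incubating"])
    nest = np.repeat(np.arange(n_nests), checks_per_nest)
    hours = rng.uniform(7.0, 17.0, rows)
    z_time = (hours - hours.mean()) / (hours.std() if rows > 1 and hours.std() > 0 else 1.0)
    eta = intercept + time_slope * z_time + rng.normal(0.0, sd_nest, n_nests)[nest]
    male = rng.random(rows) < 1.0 / (1.0 + np.exp(-eta))
    return pd.DataFrame(
        {
            "nest_id": [f"wb-{j:03d}" for j in nest],
            "time_of_day": hours,
            "sex_incubating": np.where(male, "male", "female"),
        }
    )


# --------------------------------------------------------------------------
# focal observations (feeding + off-time)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FeedingTruth:
    """Generating parameters for focal-observation streams.

    ``log_rates`` maps (species, sex) to the baseline log feeding visits per
    minute; ``-inf`` marks a non-provisioning stratum (female black coucals,
    whose feeding rate was zero at 75 of 76 nests) and yields all-zero
    counts.  Slopes act per SD of the covariate on the log-link scale.
    Off-times are modelled as a clamped Gaussian proportion of the watch
    spent perched high on bushes or grasses.
    """

    log_rates: dict = field(
        default_factory=lambda: {
            (BLACK, "male"): math.log(3.8 / 60.0),
            (BLACK, "female"): -math.inf,
            (WHITE_BROWED, "male"): math.log(0.95 / 60.0),
            (WHITE_BROWED, "female"): math.log(0.95 / 60.0),
        }
    )
    brood_mass_slope: float = 0.31
    time_slope: float = -0.01
    sd_parent: float = 0.30
    sd_nest: float = 0.30
    offtime_means: dict = field(
        default_factory=lambda: {
            (BLACK, "male"): 0.10,
            (BLACK, "female"): 0.40,
            (WHITE_BROWED, "male"): 0.25,
            (WHITE_BROWED, "female"): 0.25,
        }
    )
    offtime_time_slope: float = -0.021
    offtime_noise_sd: float = 0.10

    def __post_init__(self) -> None:
        if self.sd_parent < 0 or self.sd_nest < 0:
            raise ValueError("random-effect SDs must be >= 0")
        if any(not 0 <= p <= 1 for p in self.offtime_means.values()):
            raise ValueError("off-time proportions must lie in [0, 1]")


@dataclass(frozen=True)
class ObservationDesign:
    """Watch plan: nests per species, watches per parent, durations (min)."""

    n_nests: dict = field(default_factory=lambda: {BLACK: 76, WHITE_BROWED: 54})
    obs_per_parent: tuple = (2, 7)
    duration_range: tuple = (30.0, 225.0)
    include_black_females: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.duration_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid watch duration range (durations must be > 0)")


def simulate_focal_observations(
    truth: FeedingTruth, design: ObservationDesign, seed: int
) -> pd.DataFrame:
    """Simulate timed nest watches for every provisioning parent.

    Visit counts are Poisson with mean ``duration * exp(eta)`` where ``eta``
    stacks the stratum baseline, standardized brood-mass and time-of-day
    effects, and lognormal parent and nest heterogeneity.  Each parent gets
    two 60-min watches plus a random number of extra watches of 30-225 min.
    Covariates are returned unscaled; brood mass is generated from nestling
    number and age through the logistic growth curve so that the brood-mass
    and the nestling-number+age parameterizations describe the same data.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for species, n_nests in design.n_nests.items():
        sexes = ["male", "female"]
        if species == BLACK and not design.include_black_females:
            sexes = ["male"]
        for j in range(n_nests):
            nest_id = f"{species[:2]}-{j:03d}"
            nest_eff = rng.normal(0.0, truth.sd_nest)
            n_nestlings = int(rng.integers(2, 5))
            for sex in sexes:
                parent_id = f"{nest_id}-{sex[0]}"
                parent_eff = rng.normal(0.0, truth.sd_parent)
                lo, hi = design.obs_per_parent
                n_obs = int(rng.integers(lo, hi + 1))
                durations = [60.0, 60.0] + list(
                    np.round(rng.uniform(*design.duration_range, max(0, n_obs - 2)))
                )
                for dur in durations[:n_obs]:
                    age = rng.uniform(2.0, 13.0)
                    a_ref, k_ref, i_ref = 85.0, 0.37, 6.0
                    brood = n_nestlings * a_ref / (1 + math.exp(-k_ref * (age - i_ref)))
                    brood = max(5.0, brood * rng.normal(1.0, 0.08))
                    hour = rng.uniform(7.0, 17.0)
                    rows.append(
                        {
                            "nest_id": nest_id,
                            "parent_id": parent_id,
                            "species": species,
                            "sex": sex,
                            "duration_min": dur,
                            "brood_mass_g": brood,
                            "n_nestlings": n_nestlings,
                            "mean_age_d": age,
                            "time_of_day": hour,
                            "_nest_eff": nest_eff,
                            "_parent_eff": parent_eff,
                        }
                    )
    obs = pd.DataFrame(rows)
    if (obs["duration_min"] <= 0).any():
        raise ValueError("watch durations must be positive")

    z_brood = (obs["brood_mass_g"] - obs["brood_mass_g"].mean()) / obs["brood_mass_g"].std()
    z_time = (obs["time_of_day"] - obs["time_of_day"].mean()) / obs["time_of_day"].std()
    base = np.array([truth.log_rates[(sp, sx)] for sp, sx in zip(obs["species"], obs["sex"])])
    eta = base + truth.brood_mass_slope * z_brood + truth.time_slope * z_time
    eta = eta + obs["_parent_eff"] + obs["_nest_eff"]
    mu = obs["duration_min"].to_numpy() * np.exp(eta.to_numpy())
    obs["feeding_visits"] = np.where(mu > 0, rng.poisson(np.where(mu > 0, mu, 1.0)), 0)

    p_off = np.array([truth.offtime_means[(sp, sx)] for sp, sx in zip(obs["species"], obs["sex"])])
    p_off = p_off + truth.offtime_time_slope * z_time.to_numpy()
    p_off = np.clip(p_off + rng.normal(0.0, truth.offtime_noise_sd, len(obs)), 0.0, 1.0)
    obs["perch_min"] = np.round(p_off * obs["duration_min"].to_numpy(), 1)

    return obs.drop(columns=["_nest_eff", "_parent_eff"])


# --------------------------------------------------------------------------
# nestling growth
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthTruth:
    """Generating parameters for one species-sex growth stream.

    Logistic curve ``mass(t) = A / (1 + exp(-K (t - I)))`` with bivariate
    normal random shifts of (A, I) at the nest and the nestling level.
    Defaults come from the field estimates in :mod:`coucal.datasets`.
    """

    A: float = 77.1
    K: float = 0.377
    I: float = 6.2
    sd_A_nest: float = 9.3
    sd_I_nest: float = 0.9
    corr_AI_nest: float = 0.8
    sd_A_nestling: float = 11.7
    sd_I_nestling: float = 0.4
    corr_AI_nestling: float = 0.4
    resid_sd: float = 4.0
    n_nests: int = 60
    nestlings_per_nest: int = 2
    ages: tuple = (1, 3, 5, 7, 9, 11, 13, 15)

    def __post_init__(self) -> None:
        if min(self.A, self.K, self.I) <= 0:
            raise ValueError("A, K, I must be positive")
        if max(abs(self.corr_AI_nest), abs(self.corr_AI_nestling)) > 1:
            raise ValueError("correlation outside [-1, 1]: covariance not PSD")
        if min(self.sd_A_nest, self.sd_I_nest, self.sd_A_nestling, self.sd_I_nestling, self.resid_sd) < 0:
            raise ValueError("SDs must be >= 0")
        if not self.ages:
            raise ValueError("measurement design is empty")

    @classmethod
    def from_field_estimates(cls, species: str, sex: str, **kw) -> "GrowthTruth":
        p, r = GROWTH_PARAMS[(species, sex)], GROWTH_RANEF[(species, sex)]
        return cls(
            A=p["A"], K=p["K"], I=p["I"],
            sd_A_nest=r["nest"]["sd_A"], sd_I_nest=r["nest"]["sd_I"],
            corr_AI_nest=r["nest"]["corr"],
            sd_A_nestling=r["nestling"]["sd_A"], sd_I_nestling=r["nestling"]["sd_I"],
            corr_AI_nestling=r["nestling"]["corr"], **kw,
        )


def _bvn(rng: np.random.Generator, n: int, sd_a: float, sd_i: float, corr: float) -> np.ndarray:
    cov = np.array(
        [[sd_a**2, corr * sd_a * sd_i], [corr * sd_a * sd_i, sd_i**2]]
    )
    # eigenvalue clip guards exact-zero SDs against tiny negative rounding
    w, v = np.linalg.eigh(cov)
    if w.min() < -1e-10:
        raise ValueError("random-effect covariance is not positive semi-definite")
    root = v * np.sqrt(np.clip(w, 0.0, None))
    return rng.standard_normal((n, 2)) @ root.T


def simulate_growth_data(
    truth: GrowthTruth,
    seed: int,
    species: str = BLACK,
    sex: str = "female",
) -> pd.DataFrame:
    """Simulate repeated nestling measurements for one species-sex group.

    Columns: ``nestling_id, nest_id, species, sex, age_d, mass_g,
    truncated``.  Negative simulated masses are truncated at 0.1 g and
    flagged rather than resampled, keeping draws reproducible.
    """
    rng = np.random.default_rng(seed)
    nest_re = _bvn(rng, truth.n_nests, truth.sd_A_nest, truth.sd_I_nest, truth.corr_AI_nest)
    rows: list[dict] = []
    ages = np.asarray(truth.ages, dtype=float)
    for j in range(truth.n_nests):
        nest_id = f"{species[:2]}{sex[0]}-n{j:03d}"
        chick_re = _bvn(
            rng, truth.nestlings_per_nest, truth.sd_A_nestling, truth.sd_I_nestling, truth.corr_AI_nestling
        )
        for c in range(truth.nestlings_per_nest):
            a = truth.A + nest_re[j, 0] + chick_re[c, 0]
            i = truth.I + nest_re[j, 1] + chick_re[c, 1]
            mu = a / (1.0 + np.exp(-truth.K * (ages - i)))
            mass = mu + rng.normal(0.0, truth.resid_sd, len(ages))
            for t, m in zip(ages, mass):
                rows.append(
                    {
                        "nestling_id": f"{nest_id}-c{c}",
                        "nest_id": nest_id,
                        "species": species,
                        "sex": sex,
                        "age_d": t,
                        "mass_g": max(m, 0.1),
                        "truncated": m < 0.1,
                    }
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# prey tallies
# --------------------------------------------------------------------------


def simulate_prey_counts(
    true_props: dict[str, float], n_items: int, seed: int
) -> dict[str, int]:
    """Multinomial prey tally with the given category proportions."""
    props = np.array(list(true_props.values()), dtype=float)
    if n_items < 0:
        raise ValueError("n_items must be >= 0")
    if abs(props.sum() - 1.0) > 1e-9 or (props < 0).any():
        raise ValueError("category proportions must be >= 0 and sum to 1")
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n_items, props) if n_items else np.zeros(len(props), int)
    return dict(zip(true_props.keys(), (int(x) for x in draws)))


def square_wave_schedule(**kw) -> IncubationSchedule:
    """Noise-free schedule with near-instant relaxation (square-wave traces)."""
    base = dict(tau_cool=1e-9, tau_warm=1e-9, noise_sd=0.0, ambient_amp=0.0)
    base.update(kw)
    return IncubationSchedule(**base)


__all__ = [
    "FeedingTruth",
    "GrowthTruth",
    "IncubationSchedule",
    "ObservationDesign",
    "simulate_focal_observations",
    "simulate_growth_data",
    "simulate_incubation_checks",
    "simulate_prey_counts",
    "simulate_temperature_trace",
    "square_wave_schedule",
]
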