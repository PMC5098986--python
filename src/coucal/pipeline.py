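"""End-to-end analysis orchestrator.

:func:`run_full_analysis` turns the five input streams (read from CSV or
freshly simulated) into a report directory: detected bouts and daily
summaries, species comparisons of incubation behaviour, the incubation-
identity model, feeding and off-time models, growth-curve tables, and the
prey-composition comparison, plus a JSON manifest recording seeds, package
versions and per-stage status.  A stage failure is recorded and the
remaining stages still run; nothing fails silently.  The report is a pure
function of (inputs, config, seeds).
"""

from __future__ import annotations

import json
import traceback
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import special

from coucal import bouts as bt
from coucal import composition as cp
from coucal import growth as gr
from coucal import io
from coucal import mixed as mx
from coucal import synth
from coucal.datasets import BLACK, PREY_COUNTS, WHITE_BROWED

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "simulate": True,
    "inputs": {},
    "bout_detection": {"drop_threshold": 2.0, "jitter_tol": 0.5},
    "feeding": {"covariate_set": "brood_mass", "s1_variant": True},
    "rope": {"epsilon": 0.05, "n_draws": 100_000},
    "growth": {"age_cap": 16.0, "response": "mass"},
    "posterior": {"n_draws": 10_000},
    "simulation": {
        "temp_nests": {BLACK: 10, WHITE_BROWED: 11},
        "logger_days": {BLACK: 4, WHITE_BROWED: 5},
        "bouts_per_day": {BLACK: 6.0, WHITE_BROWED: 2.0},
        "bout_mean_min": {BLACK: 14.0, WHITE_BROWED: 24.0},
        "incubation": {
            "intercept": float(special.logit(0.809)),
            "time_slope": 0.64,
            "sd_nest": 2.0,
            "n_nests": 28,
            "checks_per_nest": 6,
        },
        "growth_nests": 60,
        "prey_items": {BLACK: 673, WHITE_BROWED: 316},
    },
}


def _deep_update(base: dict, upd: dict) -> dict:
    out = dict(base)
    for k, v in upd.items():
        out[k] = _deep_update(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(config=None) -> dict:
    """Merge a YAML path / dict over the defaults."""
    if config is None:
        return json.loads(json.dumps(DEFAULT_CONFIG))
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise TypeError("config must be a mapping or a YAML file path")
    return _deep_update(json.loads(json.dumps(DEFAULT_CONFIG)), config)


def simulate_inputs(cfg: dict, seed: int) -> dict:
    """Generate all five input streams with the configured truth."""
    sim = cfg["simulation"]
    rng = np.random.default_rng(seed)
    traces, truths = [], []
    for species in (BLACK, WHITE_BROWED):
        for j in range(sim["temp_nests"][species]):
            sched = synth.IncubationSchedule(
                bouts_per_day=sim["bouts_per_day"][species],
                bout_mean_min=sim["bout_mean_min"][species],
            )
            trace, truth = synth.simulate_temperature_trace(
                sched,
                n_days=sim["logger_days"][species],
                seed=int(rng.integers(2**31 - 1)),
                nest_id=f"{species[:2]}-temp-{j:02d}",
            )
            trace["species"] = species
            truth["species"] = species
            traces.append(trace)
            truths.append(truth)
    inc = sim["incubation"]
    checks = synth.simulate_incubation_checks(
        intercept=inc["intercept"],
        time_slope=inc["time_slope"],
        sd_nest=inc["sd_nest"],
        n_nests=inc["n_nests"],
        checks_per_nest=inc["checks_per_nest"],
        seed=int(rng.integers(2**31 - 1)),
    )
    focal = synth.simulate_focal_observations(
        synth.FeedingTruth(), synth.ObservationDesign(), seed=int(rng.integers(2**31 - 1))
    )
    growth_frames = []
    for species in (BLACK, WHITE_BROWED):
        for sex in ("female", "male"):
            truth = synth.GrowthTruth.from_field_estimates(
                species, sex, n_nests=int(sim["growth_nests"])
            )
            growth_frames.append(
                synth.simulate_growth_data(
                    truth, seed=int(rng.integers(2**31 - 1)), species=species, sex=sex
                )
            )
    nestlings = pd.concat(growth_frames, ignore_index=True)
    prey = {}
    for species in (BLACK, WHITE_BROWED):
        tallies = PREY_COUNTS[species]
        total = sum(tallies.values())
        props = {k: v / total for k, v in tallies.items()}
        prey[species] = synth.simulate_prey_counts(
            props, sim["prey_items"][species], seed=int(rng.integers(2**31 - 1))
        )
    return {
        "temperature": pd.concat(traces, ignore_index=True),
        "temperature_truth": pd.concat(truths, ignore_index=True),
        "incubation_checks": checks,
        "focal_observations": focal,
        "nestling_measurements": nestlings,
        "prey_counts": prey,
    }


def load_inputs(cfg: dict) -> dict:
    paths = cfg["inputs"]
    for stream in (
        "temperature",
        "incubation_checks",
        "focal_observations",
        "nestling_measurements",
        "prey_counts",
    ):
        if stream not in paths:
            raise KeyError(f"config names no path for input stream '{stream}'")
        io.ensure_exists(paths[stream], stream)
    return {
        "temperature": io.read_temperature(paths["temperature"]),
        "incubation_checks": io.read_checks(paths["incubation_checks"]),
        "focal_observations": io.read_focal(paths["focal_observations"]),
        "nestling_measurements": io.read_nestlings(paths["nestling_measurements"]),
        "prey_counts": io.read_prey(paths["prey_counts"]),
    }


def _lincomb_cri(fit: mx.ModelFit, combos: dict[str, np.ndarray], transform=None) -> pd.DataFrame:
    """Posterior mean and 95% CrI of linear combinations of fixed effects."""
    assert fit.draws is not None, "run posterior_sim first"
    rows = []
    for label, vec in combos.items():
        d = fit.draws @ np.asarray(vec, dtype=float)
        if transform is not None:
            d = transform(d)
        lo, hi = np.percentile(d, [2.5, 97.5])
        rows.append({"group": label, "mean": float(np.mean(d)), "cri_lo": float(lo), "cri_hi": float(hi)})
    return pd.DataFrame(rows)


def _combo(names: list[str], want: dict[str, float]) -> np.ndarray:
    v = np.zeros(len(names))
    for nm, c in want.items():
        if nm in names:
            v[names.index(nm)] = c
    return v


def _stratum_combos(names: list[str]) -> dict[str, np.ndarray]:
    return {
        "black male": _combo(names, {"intercept": 1}),
        "black female": _combo(names, {"intercept": 1, "sex_female": 1}),
        "white-browed male": _combo(names, {"intercept": 1, "species_wb": 1}),
        "white-browed female": _combo(
            names, {"intercept": 1, "species_wb": 1, "sex_female": 1, "species_wb:sex_female": 1}
        ),
    }


def run_full_analysis(config=None, out_dir="results/report") -> dict:
    """Run every stage and write the report bundle under ``out_dir``."""
    cfg = load_config(config)
    seed = int(cfg["seed"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    status: dict[str, str] = {}
    report: dict = {"config": cfg, "status": status}
    n_post = int(cfg["posterior"]["n_draws"])

    def stage(name):
        def deco(fn):
            try:
                fn()
                status[name] = "ok"
            except Exception as exc:  # recorded, never silent
                status[name] = f"failed: {exc!r}"
                report.setdefault("errors", {})[name] = traceback.format_exc()
            return fn

        return deco

    # ---- inputs -----------------------------------------------------------
    if cfg["simulate"]:
        data = simulate_inputs(cfg, seed)
        status["inputs"] = "simulated"
    else:
        data = load_inputs(cfg)  # missing files raise here, by stream name
        status["inputs"] = "loaded"

    # ---- bout detection ---------------------------------------------------
    daily_all = []

    @stage("bout_detection")
    def _bouts():
        det = cfg["bout_detection"]
        all_bouts = []
        for nest_id, trace in data["temperature"].groupby("nest_id"):
            blist = bt.detect_absence_bouts(
                trace, drop_threshold=det["drop_threshold"], jitter_tol=det["jitter_tol"]
            )
            all_bouts.extend(blist)
            cov = bt.daily_coverage(trace)
            daily = bt.summarize_daily(blist, cov)
            if "species" in trace:
                daily["species"] = trace["species"].iloc[0]
            daily_all.append(daily)
        bt.bouts_to_frame(all_bouts).to_csv(out / "bouts.csv", index=False)
        pd.concat(daily_all, ignore_index=True).to_csv(out / "daily_summary.csv", index=False)

    # ---- incubation LMMs --------------------------------------------------
    @stage("incubation_lmms")
    def _lmms():
        daily = pd.concat(daily_all, ignore_index=True)
        rows = []
        for resp in ("n_bouts", "total_absence", "bout_duration"):
            fit = mx.fit_lmm(daily, response=resp)
            mx.posterior_sim(fit, n_draws=n_post, seed=seed + 11)
            r2m, r2c = mx.r_squared(fit)
            combos = {
                "black": _combo(fit.param_names, {"intercept": 1}),
                "white-browed": _combo(fit.param_names, {"intercept": 1, "species_wb": 1}),
                "contrast wb-bl": _combo(fit.param_names, {"species_wb": 1}),
            }
            tab = _lincomb_cri(fit, combos)
            tab.insert(0, "response", resp)
            tab["r2_marginal"], tab["r2_conditional"] = r2m, r2c
            rows.append(tab)
        pd.concat(rows, ignore_index=True).to_csv(out / "incubation_comparison.csv", index=False)

    # ---- incubation identity GLMM ----------------------------------------
    @stage("incubation_glmm")
    def _glmm():
        fit = mx.fit_binomial_glmm(data["incubation_checks"])
        mx.posterior_sim(fit, n_draws=n_post, seed=seed + 13)
        r2m, r2c = mx.r_squared(fit)
        tab = _lincomb_cri(
            fit,
            {"p_male": _combo(fit.param_names, {"intercept": 1})},
            transform=special.expit,
        )
        slope = _lincomb_cri(fit, {"time_slope": _combo(fit.param_names, {"time_c": 1})})
        tab = pd.concat([tab, slope], ignore_index=True)
        tab["r2_marginal"], tab["r2_conditional"] = r2m, r2c
        tab.to_csv(out / "incubation_identity.csv", index=False)

    # ---- feeding model (+ S1 variant) -------------------------------------
    @stage("feeding_glmm")
    def _feeding():
        tabs = []
        variants = ["brood_mass"] + (["nestlings_age"] if cfg["feeding"]["s1_variant"] else [])
        for variant in variants:
            fit = mx.fit_poisson_glmm(data["focal_observations"], covariate_set=variant)
            mx.posterior_sim(fit, n_draws=n_post, seed=seed + 17)
            r2m, r2c = mx.r_squared(fit)
            combos = _stratum_combos(fit.param_names)
            dropped = fit.flags.get("dropped_zero_strata", [])
            for sp, sx in dropped:
                combos.pop(f"{sp} {sx}", None)
            tab = _lincomb_cri(fit, combos, transform=lambda d: 60.0 * np.exp(d))
            tab["unit"] = "visits/h"
            slopes = _lincomb_cri(
                fit,
                {
                    nm: _combo(fit.param_names, {nm: 1})
                    for nm in fit.param_names
                    if nm.endswith("_z")
                },
            )
            slopes["unit"] = "per SD (log scale)"
            tab = pd.concat([tab, slopes], ignore_index=True)
            tab.insert(0, "covariate_set", variant)
            tab["r2_marginal"], tab["r2_conditional"] = r2m, r2c
            tab["dropped_strata"] = "; ".join(" ".join(d) for d in dropped)
            tabs.append(tab)
        pd.concat(tabs, ignore_index=True).to_csv(out / "feeding_rates.csv", index=False)

    # ---- off-time model ----------------------------------------------------
    @stage("offtime_model")
    def _offtime():
        fit = mx.fit_offtime_model(data["focal_observations"])
        mx.posterior_sim(fit, n_draws=n_post, seed=seed + 19)
        r2m, r2c = mx.r_squared(fit)
        tab = _lincomb_cri(fit, _stratum_combos(fit.param_names))
        tab["unit"] = "proportion of watch"
        slopes = _lincomb_cri(
            fit,
            {nm: _combo(fit.param_names, {nm: 1}) for nm in fit.param_names if nm.endswith("_z")},
        )
        slopes["unit"] = "per SD"
        tab = pd.concat([tab, slopes], ignore_index=True)
        tab["r2_marginal"], tab["r2_conditional"] = r2m, r2c
        tab.to_csv(out / "offtimes.csv", index=False)

    # ---- growth curves -----------------------------------------------------
    @stage("growth_model")
    def _growth():
        g = cfg["growth"]
        fits = gr.fit_growth_by_group(
            data["nestling_measurements"], response=g["response"], age_cap=g["age_cap"]
        )
        t2, t3 = [], []
        for (sp, sx), fit in fits.items():
            row = {"species": sp, "sex": sx}
            for nm in ("K", "I", "A"):
                row[nm] = fit.params[nm]
                row[f"{nm}_lo"], row[f"{nm}_hi"] = fit.ci[nm]
            row["resid_sd"] = fit.resid_sd
            row["converged"] = fit.converged
            t2.append(row)
            re = gr.re_correlations(fit)
            re.insert(0, "sex", sx)
            re.insert(0, "species", sp)
            t3.append(re)
        pd.DataFrame(t2).to_csv(out / "growth_params.csv", index=False)
        pd.concat(t3, ignore_index=True).to_csv(out / "growth_ranef.csv", index=False)

    # ---- prey composition --------------------------------------------------
    @stage("prey_composition")
    def _prey():
        r = cfg["rope"]
        props, ropes = cp.composition_table(
            data["prey_counts"], epsilon=r["epsilon"], n_draws=r["n_draws"], seed=seed + 23
        )
        props.to_csv(out / "prey_proportions.csv", index=False)
        ropes.to_csv(out / "prey_rope.csv", index=False)

    # ---- manifest ----------------------------------------------------------
    import scipy

    import coucal

    manifest = {
        "seed": seed,
        "status": status,
        "versions": {
            "coucal": coucal.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
        "config": cfg,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    report["manifest"] = manifest
    report["out_dir"] = str(out)
    return report


__all__ = ["DEFAULT_CONFIG", "load_config", "run_full_analysis", "simulate_inputs"]
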