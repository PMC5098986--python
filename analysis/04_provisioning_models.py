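#!/usr/bin/env python
"""Feeding rates and off-times of provisioning parents.

Fits the Poisson GLMM of feeding visits (log watch duration as offset,
species x sex fixed effects, standardized brood mass and time of day,
crossed parent/nest random intercepts), its variant replacing brood mass
with nestling number + mean age, and the duration-weighted Gaussian model
of the perched ("off-time") proportion.  Back-transforms stratum estimates
to visits per hour.
"""

import json
from pathlib import Path

import numpy as np

from coucal import io, mixed

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    obs = io.read_focal(ROOT / "data" / "focal_observations.csv")
    results = {}
    for variant in ("brood_mass", "nestlings_age"):
        fit = mixed.fit_poisson_glmm(obs, covariate_set=variant)
        mixed.posterior_sim(fit, n_draws=10_000, seed=SEED)
        r2 = mixed.r_squared(fit)
        est = dict(zip(fit.param_names, fit.params))
        per_h = {
            "black male": 60 * np.exp(est["intercept"]),
            "wb male": 60 * np.exp(est["intercept"] + est.get("species_wb", 0.0)),
            "wb female": 60 * np.exp(
                est["intercept"] + est.get("species_wb", 0.0) + est.get("sex_female", 0.0)
                + est.get("species_wb:sex_female", 0.0)
            ),
        }
        print(f"feeding ({variant}): " + ", ".join(f"{k} {v:.2f}/h" for k, v in per_h.items()))
        if variant == "brood_mass":
            lo, hi = fit.cri["brood_mass_z"]
            print(f"  brood-mass slope {est['brood_mass_z']:.2f} [{lo:.2f}-{hi:.2f}] per SD, "
                  f"R2m {r2[0]:.2f} R2c {r2[1]:.2f}; dropped strata: "
                  f"{fit.flags.get('dropped_zero_strata')}")
        d = fit.to_dict()
        d["r2"] = list(r2)
        d["visits_per_hour"] = per_h
        results[f"feeding_{variant}"] = d

    ofit = mixed.fit_offtime_model(obs)
    mixed.posterior_sim(ofit, n_draws=10_000, seed=SEED + 1)
    r2 = mixed.r_squared(ofit)
    est = dict(zip(ofit.param_names, ofit.params))
    props = {
        "black male": est["intercept"],
        "wb male": est["intercept"] + est["species_wb"],
        "wb female": est["intercept"] + est["species_wb"] + est["sex_female"]
        + est.get("species_wb:sex_female", 0.0),
    }
    print("off-time proportions: " + ", ".join(f"{k} {v:.2f}" for k, v in props.items()))
    lo, hi = ofit.cri["time_z"]
    print(f"  time-of-day slope {est['time_z']:.3f} [{lo:.3f} to {hi:.3f}] per SD, "
          f"R2m {r2[0]:.2f} R2c {r2[1]:.2f}")
    d = ofit.to_dict()
    d["r2"] = list(r2)
    d["proportions"] = props
    results["offtime"] = d
    (ROOT / "provisioning_fits.json").write_text(json.dumps(results, indent=2))


if __name__ == "__main__":
    main()
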