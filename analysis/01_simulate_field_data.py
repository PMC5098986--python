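#!/usr/bin/env python
"""Generate the five synthetic input streams with known ground truth.

Stands in for the field data: nest-temperature logger traces for 10 black
and 11 white-browed coucal nests, diurnal incubation-identity checks at 28
white-browed nests, timed focal watches at 76 + 54 nests, repeated nestling
measurements for all four species-sex groups at the published growth
parameters, and multinomial prey tallies.  Writes CSVs under
results/data/ plus the generating truth for the logger traces.
"""

from pathlib import Path

from coucal import io, pipeline

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = pipeline.load_config({"seed": SEED})
    data = pipeline.simulate_inputs(cfg, SEED)
    data["temperature"].to_csv(OUT / "temperature.csv", index=False)
    data["temperature_truth"].to_csv(OUT / "temperature_truth.csv", index=False)
    data["incubation_checks"].to_csv(OUT / "incubation_checks.csv", index=False)
    data["focal_observations"].to_csv(OUT / "focal_observations.csv", index=False)
    data["nestling_measurements"].to_csv(OUT / "nestling_measurements.csv", index=False)
    io.write_prey(data["prey_counts"], OUT / "prey_counts.csv")
    print(f"seed {SEED}:")
    print(f"  {data['temperature']['nest_id'].nunique()} logger nests, "
          f"{len(data['temperature'])} temperature samples, "
          f"{len(data['temperature_truth'])} true off-bouts")
    print(f"  {len(data['incubation_checks'])} incubation checks, "
          f"{len(data['focal_observations'])} focal watches, "
          f"{len(data['nestling_measurements'])} nestling measurements")
    print(f"wrote inputs to {OUT}")


if __name__ == "__main__":
    main()
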