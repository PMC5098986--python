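"""CSV schemas for the five input streams, with load-time validation."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

TEMPERATURE_COLS = ["nest_id", "timestamp", "temp_c"]
CHECK_COLS = ["nest_id", "time_of_day", "sex_incubating"]
FOCAL_COLS = [
    "nest_id", "parent_id", "species", "sex", "duration_min",
    "feeding_visits", "perch_min", "brood_mass_g", "time_of_day",
]
NESTLING_COLS = ["nestling_id", "nest_id", "species", "sex", "age_d", "mass_g"]
PREY_COLS = ["species", "category", "count"]


def _require(df: pd.DataFrame, cols: list[str], what: str) -> pd.DataFrame:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} file lacks columns: {missing}")
    return df


def read_temperature(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    return _require(df, TEMPERATURE_COLS, "temperature trace")


def read_checks(path) -> pd.DataFrame:
    df = _require(pd.read_csv(path), CHECK_COLS, "incubation checks")
    if ((df["time_of_day"] < 0) | (df["time_of_day"] >= 24)).any():
        raise ValueError("time_of_day must lie in [0, 24) hours")
    return df


def read_focal(path) -> pd.DataFrame:
    df = _require(pd.read_csv(path), FOCAL_COLS, "focal observations")
    if (df["duration_min"] <= 0).any():
        raise ValueError("watch duration must be positive")
    bad = df["perch_min"] > df["duration_min"]
    if bad.any():
        raise ValueError(f"{int(bad.sum())} rows have perch time exceeding watch duration")
    return df


def read_nestlings(path) -> pd.DataFrame:
    df = _require(pd.read_csv(path), NESTLING_COLS, "nestling measurements")
    if (df["age_d"] < 0).any() or (df["mass_g"] <= 0).any():
        raise ValueError("ages must be >= 0 and masses positive")
    moves = df.groupby("nestling_id")["nest_id"].nunique()
    if (moves > 1).any():
        raise ValueError("a nestling appears in more than one nest")
    return df


def read_prey(path) -> dict[str, dict[str, int]]:
    df = _require(pd.read_csv(path), PREY_COLS, "prey counts")
    if (df["count"] < 0).any():
        raise ValueError("prey counts must be non-negative")
    return {
        sp: dict(zip(sub["category"], sub["count"].astype(int)))
        for sp, sub in df.groupby("species")
    }


def write_prey(prey: dict[str, dict[str, int]], path) -> None:
    rows = [
        {"species": sp, "category": cat, "count": n}
        for sp, counts in prey.items()
        for cat, n in counts.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def ensure_exists(path, stream: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"input stream '{stream}' not found at {p}")
    return p
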