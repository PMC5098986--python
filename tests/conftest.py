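import numpy as np
import pandas as pd
import pytest

from coucal import synth


def make_trace(temps, start="2006-02-01 08:00", cadence_min=3.0, nest_id="T1"):
    """Hand-built trace helper used across bout-detection tests."""
    t0 = pd.Timestamp(start)
    stamps = t0 + pd.to_timedelta(np.arange(len(temps)) * cadence_min, unit="m")
    return pd.DataFrame({"nest_id": nest_id, "timestamp": stamps, "temp_c": list(map(float, temps))})


@pytest.fixture(scope="session")
def focal_obs():
    """One moderately sized focal-observation dataset shared by model tests."""
    design = synth.ObservationDesign(
        n_nests={"black": 30, "white-browed": 25}, obs_per_parent=(2, 4)
    )
    return synth.simulate_focal_observations(synth.FeedingTruth(), design, seed=2024)


@pytest.fixture(scope="session")
def growth_data():
    truth = synth.GrowthTruth.from_field_estimates("black", "female", n_nests=60)
    return truth, synth.simulate_growth_data(truth, seed=31, species="black", sex="female")
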