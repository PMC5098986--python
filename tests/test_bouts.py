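"""Bout detector: hand-built traces, brute-force oracle, generator truth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coucal import synth
from coucal.bouts import (
    assign_tod_bin,
    daily_coverage,
    detect_absence_bouts,
    match_bouts,
    summarize_daily,
)
from conftest import make_trace


def brute_force_bouts(temp, drop_threshold=2.0, jitter_tol=0.5):
    """Naive re-statement of the bout rule, scanned sample by sample.

    For every candidate anchor, replay the decline-run definition literally
    (falls or plateaus continue the run; an isolated uptick <= jitter_tol is
    tolerated; two in a row end it); once the cumulative fall from the
    anchor reaches the threshold the bout is open, and it closes at the
    first sample that has risen ``drop_threshold`` above the running
    minimum.  Returns (start, end) index pairs; an open bout ends at the
    last index with an open flag.
    """
    out = []
    n = len(temp)
    i = 1
    while i < n:
        if temp[i] < temp[i - 1]:
            anchor = temp[i - 1]
            low = temp[i]
            j = i
            uptick = False
            while anchor - low < drop_threshold:
                if j + 1 >= n:
                    break
                d = temp[j + 1] - temp[j]
                if d < 0 or d == 0:
                    uptick = False if d < 0 else uptick
                elif d <= jitter_tol and not uptick:
                    uptick = True
                else:
                    break
                j += 1
                low = min(low, temp[j])
            if anchor - low >= drop_threshold:
                k = j
                closed = False
                while k + 1 < n:
                    k += 1
                    low = min(low, temp[k])
                    if temp[k] >= low + drop_threshold:
                        closed = True
                        break
                out.append((i, k, not closed))
                i = k + 1
                continue
        i += 1
    return out


def detector_index_pairs(trace, **kw):
    times = pd.DatetimeIndex(trace["timestamp"])
    lookup = {t: i for i, t in enumerate(times)}
    return [
        (lookup[b.start], lookup[b.end], b.open_end)
        for b in detect_absence_bouts(trace, day_window=(0.0, 24 * 60.0), **kw)
    ]


def test_flat_trace_has_no_bouts():
    assert detect_absence_bouts(make_trace([34.0] * 40)) == []


def test_square_wave_single_bout():
    temps = [34.0] * 10 + [24.0] * 10 + [34.0] * 20
    bouts = detect_absence_bouts(make_trace(temps))
    assert len(bouts) == 1
    b = bouts[0]
    assert b.duration_min == pytest.approx(30.0)  # samples 10..20 at 3 min
    assert b.min_temp == pytest.approx(24.0)
    assert not b.open_end
    # start is the first low sample, end the first recovered sample
    assert b.start == make_trace(temps)["timestamp"].iloc[10]
    assert b.end == make_trace(temps)["timestamp"].iloc[20]


def test_subthreshold_drop_ignored():
    temps = [34.0] * 5 + [32.5] * 5 + [34.0] * 5  # 1.5 degC < the 2 degC rule
    assert detect_absence_bouts(make_trace(temps)) == []


def test_empty_trace_raises():
    with pytest.raises(ValueError):
        detect_absence_bouts(make_trace([]))


def test_open_bout_flagged_and_excluded_from_summaries():
    temps = [34.0] * 10 + list(np.linspace(33, 24, 10))  # never recovers
    trace = make_trace(temps)
    bouts = detect_absence_bouts(trace)
    assert len(bouts) == 1 and bouts[0].open_end
    daily = summarize_daily(bouts, daily_coverage(trace))
    assert daily["n_bouts"].sum() == 0 and daily["total_absence_min"].sum() == 0


def test_shift_invariance():
    rng = np.random.default_rng(7)
    sched = synth.IncubationSchedule()
    trace, _ = synth.simulate_temperature_trace(sched, 2, seed=50)
    shifted = trace.copy()
    shifted["temp_c"] += 7.25
    assert detector_index_pairs(trace) == detector_index_pairs(shifted)


@pytest.mark.parametrize("seed", range(20))
def test_detector_equals_brute_force_oracle(seed):
    """Single-pass detector == literal rule replay on random traces."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(50, 500))
    # rough random walk with occasional plunges, quantized like a logger
    temp = 34.0 + np.cumsum(rng.normal(0, 0.7, n))
    for _ in range(int(rng.integers(0, 4))):
        s = int(rng.integers(0, n - 10))
        temp[s : s + int(rng.integers(3, 10))] -= rng.uniform(3, 12)
    temp = np.round(temp / 0.5) * 0.5
    trace = make_trace(temp)
    got = detector_index_pairs(trace)
    want = brute_force_bouts(temp)
    assert got == want


def test_noise_free_truth_recovered_exactly():
    """Square-wave generator truth == detector output, summaries included."""
    sched = synth.square_wave_schedule(bouts_per_day=6.0)
    trace, truth = synth.simulate_temperature_trace(sched, 4, seed=99)
    bouts = detect_absence_bouts(trace)
    recall, precision = match_bouts(bouts, truth)
    assert recall == 1.0 and precision == 1.0
    det = sorted((b.start, b.end) for b in bouts)
    tru = sorted(zip(truth["start"], truth["end"]))
    assert det == tru  # grid-exact timestamps
    daily = summarize_daily(bouts, daily_coverage(trace))
    by_day = truth.groupby(truth["start"].dt.date)["duration_min"].agg(["count", "sum"])
    for _, row in daily.iterrows():
        if row["date"] in by_day.index:
            assert row["n_bouts"] == by_day.loc[row["date"], "count"]
            assert row["total_absence_min"] == pytest.approx(by_day.loc[row["date"], "sum"])


def test_noisy_trace_recall():
    """With 0.25 degC noise and ~9 degC amplitude, recall stays >= 0.95."""
    sched = synth.IncubationSchedule(noise_sd=0.25)
    hits, total = 0, 0
    for seed in range(5):
        trace, truth = synth.simulate_temperature_trace(sched, 4, seed=200 + seed)
        bouts = detect_absence_bouts(trace)
        recall, _ = match_bouts(bouts, truth)
        hits += recall * len(truth)
        total += len(truth)
    assert hits / total >= 0.95


@given(st.integers(min_value=0, max_value=24 * 60 - 1))
@settings(max_examples=60, deadline=None)
def test_tod_bins_partition_day_window(minute):
    ts = pd.Timestamp("2006-02-01") + pd.Timedelta(minutes=minute)
    b = assign_tod_bin(ts)
    if 360 <= minute < 1170:
        assert b in {"morning", "noon", "afternoon"}
    else:
        assert b is None


def test_tod_bin_boundaries():
    assert assign_tod_bin(pd.Timestamp("2006-02-01 10:29")) == "morning"
    assert assign_tod_bin(pd.Timestamp("2006-02-01 10:30")) == "noon"
    assert assign_tod_bin(pd.Timestamp("2006-02-01 05:00")) is None


def test_daily_summary_additivity():
    temps = (
        [34.0] * 20
        + [24.0] * 4 + [34.0] * 20   # 12-min bout
        + [24.0] * 6 + [34.0] * 20   # 18-min bout
    )
    trace = make_trace(temps, start="2006-02-01 08:00")
    daily = summarize_daily(detect_absence_bouts(trace), daily_coverage(trace))
    assert daily["n_bouts"].iloc[0] == 2
    assert daily["total_absence_min"].iloc[0] == pytest.approx(30.0)


def test_bin_counts_sum_to_total():
    """Bouts lying fully inside the diurnal window always get a bin, and
    per-bin counts add up to their total."""
    sched = synth.IncubationSchedule(noise_sd=0.25)
    trace, _ = synth.simulate_temperature_trace(sched, 3, seed=77)
    bouts = [b for b in detect_absence_bouts(trace) if not b.open_end]

    def clock(ts):
        return ts.hour * 60 + ts.minute + ts.second / 60

    fully_inside = [
        b for b in bouts if clock(b.start) >= 360 and clock(b.end) < 1170
    ]
    assert fully_inside  # the diurnal generator puts nearly all bouts here
    assert all(b.tod_bin is not None for b in fully_inside)
    per_bin = {}
    for b in fully_inside:
        per_bin[b.tod_bin] = per_bin.get(b.tod_bin, 0) + 1
    assert sum(per_bin.values()) == len(fully_inside)
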