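"""Incubation absence-bout detection from nest-temperature traces.

An absence bout ("off-bout") starts with a steady drop of at least
``drop_threshold`` (default 2 degC) in the logger reading and ends when the
reading has risen ``drop_threshold`` above the minimum recorded during the
bout.  "Steady drop" is operationalized as a decline run: consecutive
samples that fall or stay level, tolerating isolated upticks no larger than
``jitter_tol`` (default one 0.5 degC quantization step) — strict
monotonicity is unusable on quantized readings.  The bout start is placed at
the first sample of the decline run; the cumulative fall is measured from
the sample immediately before the run.

Only the diurnal window (default 06:00-19:30, the outer bounds of the
morning/noon/afternoon observation bins) is analysed; bouts entirely outside
it are discarded.  A bout still open when the trace ends is emitted with an
``open_end`` flag and excluded from duration summaries.  A new temperature
drop beginning before a prior bout's recovery criterion is met is treated as
the same, ongoing bout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Half-open diurnal bins (minutes since midnight).
TOD_BINS = (
    ("morning", 6 * 60.0, 10.5 * 60.0),
    ("noon", 10.5 * 60.0, 15 * 60.0),
    ("afternoon", 15 * 60.0, 19.5 * 60.0),
)

DAY_WINDOW = (6 * 60.0, 19.5 * 60.0)


def assign_tod_bin(timestamp) -> str | None:
    """Diurnal bin of a timestamp: morning [06:00, 10:30), noon
    [10:30, 15:00), afternoon [15:00, 19:30); ``None`` outside."""
    ts = pd.Timestamp(timestamp)
    minute = ts.hour * 60.0 + ts.minute + ts.second / 60.0
    for name, lo, hi in TOD_BINS:
        if lo <= minute < hi:
            return name
    return None


@dataclass(frozen=True)
class AbsenceBout:
    """One detected interruption of incubation."""

    nest_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    duration_min: float
    min_temp: float
    date: object
    tod_bin: str | None
    open_end: bool = False
    unreliable: bool = False


def _clock_minutes(ts: pd.Timestamp) -> float:
    return ts.hour * 60.0 + ts.minute + ts.second / 60.0


def detect_absence_bouts(
    trace: pd.DataFrame,
    drop_threshold: float = 2.0,
    jitter_tol: float = 0.5,
    day_window: tuple[float, float] = DAY_WINDOW,
) -> list[AbsenceBout]:
    """Detect absence bouts in one nest's temperature trace.

    ``trace`` needs columns ``nest_id, timestamp, temp_c`` with strictly
    increasing timestamps at a nominally constant cadence.  The detector is
    a single forward scan; it is invariant under adding a constant to every
    temperature because the rule only uses differences.  Bouts containing a
    cadence gap larger than twice the nominal sampling interval are flagged
    ``unreliable``.
    """
    if len(trace) == 0:
        raise ValueError("empty temperature trace")
    if drop_threshold <= 0:
        raise ValueError("drop_threshold must be positive")
    times = pd.DatetimeIndex(trace["timestamp"])
    if len(times) > 1 and not (np.diff(times.asi8) > 0).all():
        raise ValueError("timestamps must be strictly increasing")
    temp = trace["temp_c"].to_numpy(dtype=float)
    nest_id = str(trace["nest_id"].iloc[0]) if "nest_id" in trace else "?"
    n = len(temp)
    dt_min = np.diff(times.asi8) / 60e9 if n > 1 else np.array([])
    nominal = float(np.median(dt_min)) if n > 1 else 0.0

    bouts: list[AbsenceBout] = []
    i = 1
    while i < n:
        if not temp[i] < temp[i - 1]:
            i += 1
            continue
        # decline run anchored at the sample before the first falling one
        ref = temp[i - 1]
        run_start = i
        low = temp[i]
        j = i
        prev_uptick = False
        gap = False
        while ref - low < drop_threshold and j + 1 < n:
            step = temp[j + 1] - temp[j]
            if step < 0:
                prev_uptick = False
            elif step == 0:
                pass
            elif step <= jitter_tol and not prev_uptick:
                prev_uptick = True
            else:
                break
            j += 1
            gap = gap or (nominal > 0 and dt_min[j - 1] > 2 * nominal)
            low = min(low, temp[j])
        if ref - low < drop_threshold:
            i = run_start + 1
            continue
        # bout confirmed: track the running minimum until recovery
        k = j
        open_end = True
        while k + 1 < n:
            k += 1
            gap = gap or (nominal > 0 and dt_min[k - 1] > 2 * nominal)
            low = min(low, temp[k])
            if temp[k] >= low + drop_threshold:
                open_end = False
                break
        start_ts, end_ts = times[run_start], times[k]
        duration = (end_ts - start_ts).total_seconds() / 60.0
        mid = start_ts + (end_ts - start_ts) / 2
        s_min, e_min = _clock_minutes(start_ts), _clock_minutes(end_ts)
        # unwrap ends past midnight so the interval is monotone in clock time
        e_adj = e_min + 1440.0 * (end_ts.date() - start_ts.date()).days
        inside = any(
            not (e_adj <= day_window[0] + shift or s_min >= day_window[1] + shift)
            for shift in (0.0, 1440.0)
        )
        if inside:
            bouts.append(
                AbsenceBout(
                    nest_id=nest_id,
                    start=start_ts,
                    end=end_ts,
                    duration_min=duration,
                    min_temp=float(low),
                    date=start_ts.date(),
                    tod_bin=assign_tod_bin(mid),
                    open_end=open_end,
                    unreliable=gap,
                )
            )
        i = k + 1
    return bouts


def bouts_to_frame(bouts: list[AbsenceBout]) -> pd.DataFrame:
    cols = ["nest_id", "start", "end", "duration_min", "min_temp", "date", "tod_bin", "open_end", "unreliable"]
    return pd.DataFrame([{c: getattr(b, c) for c in cols} for b in bouts], columns=cols)


def daily_coverage(
    trace: pd.DataFrame, day_window: tuple[float, float] = DAY_WINDOW
) -> pd.DataFrame:
    """Per calendar day, the fraction of the diurnal window the logger covers."""
    times = pd.DatetimeIndex(trace["timestamp"])
    nominal = float(np.median(np.diff(times.asi8) / 60e9)) if len(times) > 1 else 3.0
    minute = times.hour * 60.0 + times.minute + times.second / 60.0
    in_win = (minute >= day_window[0]) & (minute < day_window[1])
    per_day = pd.Series(in_win, index=times).groupby(times.date).sum()
    need = (day_window[1] - day_window[0]) / nominal
    cov = pd.DataFrame({"date": per_day.index, "coverage": per_day.to_numpy() / need})
    cov["partial"] = cov["coverage"] < 0.999
    return cov


def summarize_daily(
    bouts: list[AbsenceBout],
    coverage: pd.DataFrame,
    day_window: tuple[float, float] = DAY_WINDOW,
) -> pd.DataFrame:
    """Daily attendance summaries for one nest.

    One row per covered day: number of bouts, total absence (min/day), and
    mean bout duration per diurnal bin (bouts assigned by midpoint).
    Open-ended and unreliable bouts are excluded.  Days with partial logger
    coverage keep their ``partial`` flag from :func:`daily_coverage`.
    """
    closed = [b for b in bouts if not b.open_end and not b.unreliable]
    nests = {b.nest_id for b in closed}
    if len(nests) > 1:
        raise ValueError("summarize_daily expects bouts from a single nest")
    nest_id = next(iter(nests)) if nests else "?"
    rows = []
    for _, day in coverage.iterrows():
        todays = [b for b in closed if b.date == day["date"]]
        row = {
            "nest_id": nest_id,
            "date": day["date"],
            "n_bouts": len(todays),
            "total_absence_min": float(sum(b.duration_min for b in todays)),
            "partial": bool(day["partial"]),
        }
        for name, _, _ in TOD_BINS:
            in_bin = [b.duration_min for b in todays if b.tod_bin == name]
            row[f"mean_dur_{name}"] = float(np.mean(in_bin)) if in_bin else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def match_bouts(
    detected: list[AbsenceBout], truth: pd.DataFrame
) -> tuple[float, float]:
    """(recall, precision) of detected bouts against a generator truth table.

    A true bout is recalled if any detected bout overlaps it in time; a
    detected bout is a true positive if it overlaps any true bout.
    """
    det = [(b.start, b.end) for b in detected]
    tru = list(zip(truth["start"], truth["end"]))

    def overlaps(a, b):
        return a[0] < b[1] and b[0] < a[1]

    recall = (
        sum(any(overlaps(t, d) for d in det) for t in tru) / len(tru) if tru else 1.0
    )
    precision = (
        sum(any(overlaps(d, t) for t in tru) for d in det) / len(det) if det else 1.0
    )
    return recall, precision


__all__ = [
    "DAY_WINDOW",
    "TOD_BINS",
    "AbsenceBout",
    "assign_tod_bin",
    "bouts_to_frame",
    "daily_coverage",
    "detect_absence_bouts",
    "match_bouts",
    "summarize_daily",
]
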