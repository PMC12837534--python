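"""Artifact-robust preprocessing: hourly maxima, day differences, STd-6h.

The ventral tail-base surface temperature (VTB-ST) stream is contaminated by
transient *cooling artifacts* — the device reads low whenever colder air
reaches the sensor (lying bouts, tail raising, rain or snow).  Because the
artifacts are strictly downward, the maximum reading within each clock hour
is a robust estimate of the undisturbed skin temperature for that hour, and
the whole chain is built on it:

1. ``hourly_max``   — highest validated reading per clock-hour bin
   ``[h:00, h+1:00)`` per mare; empty bins stay missing, never zero-filled.
2. ``day_diffs``    — same-clock-hour differences versus one day earlier
   (STd1) and two days earlier (STd2); differencing at the same clock hour
   removes the circadian baseline and any constant per-mare sensor bias.
3. ``std6h``        — the alert statistic: the unweighted mean of all STd1
   and STd2 values (up to 12) from the 6 hour-bins preceding the evaluation
   instant (study protocol: bins 9:00..14:00 evaluated at 15:00 daily).

A day is *evaluable* only when at least ``min_coverage`` of the 12 possible
differences exist (default 12, i.e. strict completeness); nothing is ever
interpolated or imputed.
"""

from __future__ import annotations

from datetime import time
from typing import Iterable

import pandas as pd

__all__ = [
    "hourly_max",
    "day_diffs",
    "std6h_at",
    "std6h_daily",
    "DEFAULT_EVAL_CLOCK",
    "DEFAULT_WINDOW_H",
    "DEFAULT_MIN_COVERAGE",
]

#: Daily evaluation instant of the study protocol.
DEFAULT_EVAL_CLOCK = time(15, 0)
#: Length of the averaging window preceding the evaluation instant, hours.
DEFAULT_WINDOW_H = 6
#: Minimum number of pooled STd1/STd2 values for an evaluable day (max 12).
DEFAULT_MIN_COVERAGE = 12

_STD6H_COLUMNS = ["mare_id", "eval_time", "std6h", "n_diffs", "evaluable"]


def hourly_max(records: pd.DataFrame) -> pd.DataFrame:
    """Reduce validated sensor records to per-mare hourly maxima.

    Parameters
    ----------
    records
        Validated records (``mare_id, timestamp, temp_c``); any sampling
        cadence is accepted, the nominal 3-min interval is never assumed.

    Returns
    -------
    DataFrame with columns ``mare_id, hour_bin, temp_max, n_records`` where
    ``hour_bin`` is the start of the half-open bin ``[h:00, h+1:00)``.
    Hours with no readings are simply absent.
    """
    if records.empty:
        return pd.DataFrame(columns=["mare_id", "hour_bin", "temp_max", "n_records"])
    out = (
        records.assign(hour_bin=records["timestamp"].dt.floor("h"))
        .groupby(["mare_id", "hour_bin"], as_index=False, sort=True)
        .agg(temp_max=("temp_c", "max"), n_records=("temp_c", "size"))
    )
    return out


def day_diffs(hourly: pd.DataFrame) -> pd.DataFrame:
    """Same-clock-hour day-over-day differences STd1 and STd2.

    For each present bin ``(d, h)``: ``std1 = M(d,h) - M(d-1,h)`` and
    ``std2 = M(d,h) - M(d-2,h)``, each defined only when both operand bins
    exist (missing operands yield NaN, never 0).
    """
    if hourly.empty:
        return pd.DataFrame(columns=["mare_id", "hour_bin", "std1", "std2"])
    base = hourly[["mare_id", "hour_bin", "temp_max"]]
    out = base.copy()
    for lag, col in ((1, "std1"), (2, "std2")):
        shifted = base.assign(hour_bin=base["hour_bin"] + pd.Timedelta(days=lag))
        shifted = shifted.rename(columns={"temp_max": "_prev"})
        out = out.merge(shifted, on=["mare_id", "hour_bin"], how="left")
        out[col] = out["temp_max"] - out.pop("_prev")
    return out[["mare_id", "hour_bin", "std1", "std2"]]


def _pool_window(
    diffs: pd.DataFrame, eval_time: pd.Timestamp, window_h: int
) -> pd.DataFrame:
    start = eval_time - pd.Timedelta(hours=window_h)
    m = (diffs["hour_bin"] >= start) & (diffs["hour_bin"] < eval_time)
    return diffs.loc[m]


def std6h_at(
    diffs: pd.DataFrame,
    eval_time: pd.Timestamp | str,
    window_h: int = DEFAULT_WINDOW_H,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """STd-6h for every mare at one evaluation instant.

    Pools all available STd1 and STd2 values from the hour bins
    ``[eval_time - window_h, eval_time)`` and takes their unweighted mean
    (the pooled form: with complete data this equals the mean of the two
    6-bin means, and it is the declared behaviour when bins are missing).

    Returns
    -------
    DataFrame ``mare_id, eval_time, std6h, n_diffs, evaluable`` with one row
    per mare present in ``diffs``; ``std6h`` is NaN when not evaluable.
    """
    if window_h <= 0:
        raise ValueError(f"window_h must be positive, got {window_h}")
    eval_time = pd.Timestamp(eval_time)
    if eval_time != eval_time.floor("h"):
        raise ValueError(f"eval_time must fall on an hour boundary, got {eval_time}")

    mares = sorted(diffs["mare_id"].unique()) if not diffs.empty else []
    window = _pool_window(diffs, eval_time, window_h)
    rows = []
    for mare in mares:
        pooled = window.loc[window["mare_id"] == mare, ["std1", "std2"]].stack().dropna()
        n = int(pooled.size)
        evaluable = n >= min_coverage
        rows.append(
            {
                "mare_id": mare,
                "eval_time": eval_time,
                "std6h": float(pooled.mean()) if evaluable else float("nan"),
                "n_diffs": n,
                "evaluable": evaluable,
            }
        )
    return pd.DataFrame(rows, columns=_STD6H_COLUMNS)


def std6h_daily(
    diffs: pd.DataFrame,
    eval_clock: time = DEFAULT_EVAL_CLOCK,
    window_h: int = DEFAULT_WINDOW_H,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """STd-6h at the daily evaluation instant for every mare-day with data.

    Each hour bin is attributed to the next daily ``eval_clock`` instant
    strictly after it; bins further than ``window_h`` hours before their
    evaluation instant are ignored.  Days whose window contains no
    differences at all are absent from the output (and therefore not
    evaluable); days with partial coverage appear with ``evaluable=False``.
    """
    if window_h <= 0:
        raise ValueError(f"window_h must be positive, got {window_h}")
    if diffs.empty:
        return pd.DataFrame(columns=_STD6H_COLUMNS)

    offset = pd.Timedelta(hours=eval_clock.hour, minutes=eval_clock.minute)
    bins = diffs["hour_bin"]
    eval_time = bins.dt.normalize() + offset
    eval_time = eval_time.where(eval_time > bins, eval_time + pd.Timedelta(days=1))
    in_window = bins >= eval_time - pd.Timedelta(hours=window_h)

    pooled = (
        diffs.loc[in_window, ["mare_id", "std1", "std2"]]
        .assign(eval_time=eval_time[in_window])
        .melt(id_vars=["mare_id", "eval_time"], value_vars=["std1", "std2"])
        .dropna(subset=["value"])
    )
    if pooled.empty:
        return pd.DataFrame(columns=_STD6H_COLUMNS)
    agg = (
        pooled.groupby(["mare_id", "eval_time"], as_index=False)
        .agg(std6h=("value", "mean"), n_diffs=("value", "size"))
    )
    agg["evaluable"] = agg["n_diffs"] >= min_coverage
    agg.loc[~agg["evaluable"], "std6h"] = float("nan")
    return agg[_STD6H_COLUMNS].sort_values(["mare_id", "eval_time"]).reset_index(drop=True)
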