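"""Day-level validation harness for the nocturnal-foaling alert.

One *mare-day* is the unit of evaluation: the daily 15:00 STd-6h value,
labelled by whether the mare foaled during the following night window
[18:00, 06:00).  A foaling after midnight is credited to the evaluation
date whose 15:00 evaluation preceded it (the calendar date of the 18:00
boundary).  Mares that foaled in daytime are excluded — the alert is
defined for nocturnal foaling only.

Per mare the validation window keeps the foaling day plus up to six
preceding consecutive evaluable days (at most seven in total); mares with
fewer than five such days are excluded.  Over that day set the harness
counts, per threshold:

* TP — foaling days with a positive alert,
* FP — non-foaling days with a positive alert,
* FN — foaling days without an alert,

and reports ``sensitivity = 100*TP/(TP+FN)`` and
``precision = 100*TP/(TP+FP)`` to one decimal (half-up).  True negatives
and specificity are computed but are not part of the headline table: with
a multi-day window per foaling the negatives dominate and specificity is
driven by the arbitrary window length rather than by the alert.

The module also provides the descriptive summaries used to characterise
the signal itself: pooled raw-temperature percentiles over 24-h periods
anchored at 15:00 before parturition, and the per-day fraction of mares
whose STd-6h lies at or below a cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import time

import numpy as np
import pandas as pd

from ._util import round_half_up

__all__ = [
    "NIGHT_START",
    "NIGHT_END",
    "label_days",
    "build_validation_window",
    "confusion",
    "confusion_sweep",
    "alerts_per_mare",
    "CircadianSummary",
    "circadian_summary",
    "std6h_distribution",
]

log = logging.getLogger(__name__)

#: Night window of the study: [18:00, 06:00 next day).
NIGHT_START = time(18, 0)
NIGHT_END = time(6, 0)

_OUTCOME_COLUMNS = [
    "mare_id", "eval_date", "std6h", "n_diffs", "evaluable", "foaling_tonight",
]


def night_eval_date(
    foaling_time: pd.Timestamp,
    night_start: time = NIGHT_START,
    night_end: time = NIGHT_END,
) -> pd.Timestamp | None:
    """Evaluation date credited with a foaling, or None for daytime foalings.

    The night window of evaluation date ``D`` is ``[D+night_start,
    D+1+night_end)`` (half-open: a foaling at exactly ``night_end`` counts
    as daytime).
    """
    clock = foaling_time.time()
    if clock >= night_start:
        return foaling_time.normalize()
    if clock < night_end:
        return foaling_time.normalize() - pd.Timedelta(days=1)
    return None


def label_days(
    std6h_days: pd.DataFrame,
    events: pd.DataFrame,
    night_start: time = NIGHT_START,
    night_end: time = NIGHT_END,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label each mare-day with its nocturnal-foaling outcome.

    Parameters
    ----------
    std6h_days
        Daily statistic table (from :func:`foalwatch.preprocess.std6h_daily`).
    events
        Foaling events (``mare_id, foaling_time``); mares without an event
        are kept with ``foaling_tonight=False`` everywhere.

    Returns
    -------
    (outcomes, excluded)
        ``outcomes`` — one row per mare-day with ``foaling_tonight``;
        days of mares with a *daytime* foaling are excluded entirely.
        ``excluded`` — one row per excluded mare with a reason code.
    """
    if night_start <= night_end:
        raise ValueError("night window must span midnight (night_start > night_end)")
    anchors: dict[str, pd.Timestamp] = {}
    excluded_rows = []
    for _, ev in events.iterrows():
        anchor = night_eval_date(pd.Timestamp(ev["foaling_time"]), night_start, night_end)
        if anchor is None:
            excluded_rows.append(
                {"mare_id": ev["mare_id"], "reason": "daytime_foaling",
                 "detail": str(ev["foaling_time"])}
            )
            log.info("mare %s excluded: daytime foaling at %s", ev["mare_id"], ev["foaling_time"])
        else:
            anchors[str(ev["mare_id"])] = anchor

    daytime = {row["mare_id"] for row in excluded_rows}
    days = std6h_days[~std6h_days["mare_id"].isin(daytime)].copy()
    if days.empty:
        outcomes = pd.DataFrame(columns=_OUTCOME_COLUMNS)
    else:
        days["eval_date"] = days["eval_time"].dt.normalize()
        anchor_series = days["mare_id"].map(anchors)
        days["foaling_tonight"] = days["eval_date"] == anchor_series
        outcomes = days[_OUTCOME_COLUMNS].reset_index(drop=True)
    excluded = pd.DataFrame(excluded_rows, columns=["mare_id", "reason", "detail"])
    return outcomes, excluded


def build_validation_window(
    outcomes: pd.DataFrame,
    max_days: int = 7,
    min_days: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict outcomes to each mare's pre-foaling validation window.

    Keeps, per mare, the foaling day plus up to ``max_days - 1`` preceding
    *consecutive* evaluable days; a gap (missing or non-evaluable day)
    truncates the window.  Mares without an evaluable foaling day or with
    fewer than ``min_days`` window days are excluded.

    Returns
    -------
    (window, excluded)
        ``window`` — the kept mare-days, flagged ``in_validation_window``;
        ``excluded`` — one row per excluded mare with a reason code.
    """
    kept = []
    excluded_rows = []
    for mare, grp in outcomes.groupby("mare_id", sort=True):
        foal_days = grp.loc[grp["foaling_tonight"]]
        if foal_days.empty:
            excluded_rows.append({"mare_id": mare, "reason": "no_foaling_day", "detail": ""})
            continue
        foal_date = foal_days["eval_date"].iloc[0]
        if not bool(foal_days["evaluable"].iloc[0]):
            excluded_rows.append(
                {"mare_id": mare, "reason": "foaling_day_not_evaluable",
                 "detail": str(foal_date.date())}
            )
            continue
        by_date = grp.set_index("eval_date")
        dates = [foal_date]
        for back in range(1, max_days):
            d = foal_date - pd.Timedelta(days=back)
            if d not in by_date.index or not bool(by_date.loc[d, "evaluable"]):
                break
            dates.append(d)
        if len(dates) < min_days:
            excluded_rows.append(
                {"mare_id": mare, "reason": "insufficient_days",
                 "detail": f"{len(dates)} evaluable consecutive day(s)"}
            )
            log.info("mare %s excluded: only %d consecutive evaluable day(s)", mare, len(dates))
            continue
        kept.append(grp.loc[grp["eval_date"].isin(dates)])

    if kept:
        window = pd.concat(kept, ignore_index=True).assign(in_validation_window=True)
        window = window.sort_values(["mare_id", "eval_date"]).reset_index(drop=True)
    else:
        window = pd.DataFrame(columns=_OUTCOME_COLUMNS + ["in_validation_window"])
    excluded = pd.DataFrame(excluded_rows, columns=["mare_id", "reason", "detail"])
    return window, excluded


def _join_alerts(
    outcomes: pd.DataFrame, decisions: pd.DataFrame, threshold: float
) -> pd.DataFrame:
    at = decisions.loc[np.isclose(decisions["threshold"], threshold)]
    joined = outcomes.merge(
        at[["mare_id", "eval_date", "alert"]], on=["mare_id", "eval_date"], how="left"
    )
    if joined["alert"].isna().any():
        missing = joined.loc[joined["alert"].isna(), ["mare_id", "eval_date"]]
        raise ValueError(
            f"decisions at threshold {threshold} do not cover all outcome days; "
            f"first missing: {missing.iloc[0].tolist()}"
        )
    joined["alert"] = joined["alert"].astype(bool)
    return joined


def confusion(
    outcomes: pd.DataFrame, decisions: pd.DataFrame, threshold: float
) -> dict:
    """TP/FP/FN counts and accuracy statistics at one threshold.

    ``outcomes`` should already be restricted to the validation window.
    ``sensitivity``/``precision`` (and the non-headline ``specificity``)
    are percentages rounded half-up to one decimal; a statistic whose
    denominator is zero is reported as NaN (absent), never as 0.
    """
    joined = _join_alerts(outcomes, decisions, threshold)
    foal = joined["foaling_tonight"].to_numpy(dtype=bool)
    alert = joined["alert"].to_numpy(dtype=bool)
    tp = int((foal & alert).sum())
    fp = int((~foal & alert).sum())
    fn = int((foal & ~alert).sum())
    tn = int((~foal & ~alert).sum())
    return {
        "threshold": threshold,
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "sensitivity": round_half_up(100.0 * tp / (tp + fn), 1) if tp + fn else float("nan"),
        "precision": round_half_up(100.0 * tp / (tp + fp), 1) if tp + fp else float("nan"),
        "specificity": round_half_up(100.0 * tn / (tn + fp), 1) if tn + fp else float("nan"),
    }


#: Headline columns of the threshold-sweep table.
_HEADLINE = ["threshold", "tp", "fp", "fn", "sensitivity", "precision"]


def confusion_sweep(
    outcomes: pd.DataFrame,
    decisions: pd.DataFrame,
    include_negatives: bool = False,
) -> pd.DataFrame:
    """One confusion row per threshold present in ``decisions``.

    The headline table mirrors the published layout (threshold, TP, FP, FN,
    sensitivity, precision); ``include_negatives=True`` appends the
    ``tn``/``specificity`` columns.
    """
    thresholds = sorted(decisions["threshold"].unique(), reverse=True)
    rows = [confusion(outcomes, decisions, t) for t in thresholds]
    table = pd.DataFrame(rows)
    cols = _HEADLINE + (["tn", "specificity"] if include_negatives else [])
    return table[cols]


def alerts_per_mare(row: dict | pd.Series, n_mares: int) -> float:
    """Average positive alerts per mare over the validation window, 1 decimal.

    ``(TP + FP) / n_mares``, rounded half-up — the operational cost of a
    threshold: how many nights per mare a manager is called out.
    """
    if n_mares <= 0:
        raise ValueError(f"n_mares must be positive, got {n_mares}")
    return round_half_up((row["tp"] + row["fp"]) / n_mares, 1)


def _percentiles(values: np.ndarray) -> dict:
    return {
        "n_values": int(values.size),
        "p25": float(np.percentile(values, 25)),
        "median": float(np.percentile(values, 50)),
        "p75": float(np.percentile(values, 75)),
    }


@dataclass
class CircadianSummary:
    """Pooled raw-temperature percentiles around parturition.

    Attributes
    ----------
    periods
        One row per 24-h period (anchored at the daily 15:00 preceding
        foaling): ``day_offset`` (-5..-1), pooled ``p25/median/p75``.
    polyline
        One row per 3-h bin along the -5d..-1d timeline
        (``day_offset, bin_start_h`` = hours since the period start).
    clock_bins
        One row per clock 3-h bin (0,3,...,21 h) pooled across all periods —
        the circadian profile used for simulator calibration.
    """

    periods: pd.DataFrame
    polyline: pd.DataFrame
    clock_bins: pd.DataFrame


def circadian_summary(
    records: pd.DataFrame,
    events: pd.DataFrame,
    day_offsets: tuple[int, ...] = (-5, -4, -3, -2, -1),
    bin_hours: int = 3,
    anchor_clock: time = time(15, 0),
) -> CircadianSummary:
    """Descriptive statistics of raw readings over the last days of pregnancy.

    Raw validated readings of all mares are pooled into 24-h periods
    starting at ``anchor_clock`` (so data after 15:00 on the day of
    parturition never enter), and into ``bin_hours``-wide sub-bins.
    Percentiles use linear interpolation.  Periods with no data are absent.
    """
    offset_td = pd.Timedelta(hours=anchor_clock.hour, minutes=anchor_clock.minute)
    frames = []
    for _, ev in events.iterrows():
        mare = str(ev["mare_id"])
        foal = pd.Timestamp(ev["foaling_time"])
        anchor = foal.normalize() + offset_td
        if anchor > foal:
            anchor -= pd.Timedelta(days=1)
        recs = records.loc[records["mare_id"] == mare]
        if recs.empty:
            continue
        rel_h = (recs["timestamp"] - anchor) / pd.Timedelta(hours=1)
        day_offset = np.floor(rel_h / 24.0).astype(int)
        keep = np.isin(day_offset, day_offsets)
        frames.append(
            pd.DataFrame(
                {
                    "temp_c": recs.loc[keep, "temp_c"].to_numpy(),
                    "day_offset": day_offset[keep],
                    "bin_start_h": (np.floor(rel_h[keep] % 24.0 / bin_hours) * bin_hours).astype(int),
                }
            )
        )
    if not frames:
        empty = pd.DataFrame()
        return CircadianSummary(empty, empty, empty)
    pooled = pd.concat(frames, ignore_index=True)

    periods = (
        pooled.groupby("day_offset")["temp_c"]
        .apply(lambda v: pd.Series(_percentiles(v.to_numpy())))
        .unstack()
        .reset_index()
    )
    polyline = (
        pooled.groupby(["day_offset", "bin_start_h"])["temp_c"]
        .apply(lambda v: pd.Series(_percentiles(v.to_numpy())))
        .unstack()
        .reset_index()
    )
    # Clock-of-day 3-h bins pooled across periods; bin_start_h counts from
    # the 15:00 anchor, so clock hour = (anchor + bin_start_h) mod 24.
    pooled["clock_h"] = (pooled["bin_start_h"] + anchor_clock.hour) % 24
    clock_bins = (
        pooled.groupby("clock_h")["temp_c"]
        .apply(lambda v: pd.Series(_percentiles(v.to_numpy())))
        .unstack()
        .reset_index()
    )
    for frame in (periods, polyline, clock_bins):
        frame["n_values"] = frame["n_values"].astype(int)
    return CircadianSummary(periods, polyline, clock_bins)


def std6h_distribution(
    outcomes: pd.DataFrame,
    cut: float = -0.2,
    day_offsets: tuple[int, ...] = (-7, -6, -5, -4, -3, -2, -1),
) -> pd.DataFrame:
    """Per-day fraction of mares whose STd-6h lies at or below ``cut``.

    ``day_offset`` is relative to the foaling evaluation day, which is -1
    (the 15:00 evaluation preceding the foaling night); -2 is the day
    before, and so on.  Only evaluable days count; an offset with no mares
    is absent.  ``fraction_below`` is a percentage rounded half-up to one
    decimal.
    """
    foal_dates = (
        outcomes.loc[outcomes["foaling_tonight"], ["mare_id", "eval_date"]]
        .rename(columns={"eval_date": "foal_date"})
    )
    merged = outcomes.merge(foal_dates, on="mare_id", how="inner")
    merged = merged.loc[merged["evaluable"]]
    merged["day_offset"] = (
        (merged["eval_date"] - merged["foal_date"]).dt.days - 1
    ).astype(int)
    merged = merged.loc[merged["day_offset"].isin(day_offsets)]
    rows = []
    for off, grp in merged.groupby("day_offset"):
        n = int(grp["mare_id"].nunique())
        below = int((grp["std6h"] <= cut).sum())
        rows.append(
            {
                "day_offset": int(off),
                "n_mares": n,
                "n_below": below,
                "fraction_below": round_half_up(100.0 * below / n, 1),
            }
        )
    return pd.DataFrame(rows, columns=["day_offset", "n_mares", "n_below", "fraction_below"])
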