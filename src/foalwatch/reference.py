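"""Published validation counts of the 22-mare field study, and a
day-level fixture reconstructed from them.

The original field study validated the STd-6h alert on 147 mare-days from
22 night-foaling heavy draft mares (22 foaling days, 125 non-foaling days;
5-7 window days per mare, mean 6.7) and printed, for each threshold of the
-0.05..-0.55 °C sweep, the TP/FP/FN counts with sensitivity and precision.
Those counts fully determine the *histogram* of day-level STd-6h values
over the threshold grid: differencing consecutive TP (FP) entries gives the
number of foaling (non-foaling) days falling between consecutive
thresholds.  :func:`reconstruct_validation_days` materialises one such
consistent day-level data set — a synthetic stand-in for the study's
per-day values, exact at the grid resolution — which lets the whole
predictor + evaluator chain be exercised against the printed table without
the study's raw data.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "VALIDATION_COUNTS",
    "N_VALIDATION_MARES",
    "N_VALIDATION_DAYS",
    "N_FOALING_DAYS",
    "published_counts",
    "reconstruct_validation_days",
]

#: Printed threshold sweep of the field validation: threshold -> (TP, FP, FN).
VALIDATION_COUNTS: dict[float, tuple[int, int, int]] = {
    -0.05: (20, 47, 2),
    -0.10: (20, 38, 2),
    -0.15: (19, 28, 3),
    -0.20: (18, 17, 4),
    -0.25: (16, 15, 6),
    -0.30: (15, 9, 7),
    -0.35: (11, 6, 11),
    -0.40: (10, 5, 12),
    -0.45: (8, 4, 14),
    -0.50: (6, 1, 16),
    -0.55: (5, 1, 17),
}

N_VALIDATION_MARES = 22
N_VALIDATION_DAYS = 147
N_FOALING_DAYS = 22


def published_counts() -> pd.DataFrame:
    """The printed TP/FP/FN sweep as a DataFrame (threshold descending)."""
    rows = [
        {"threshold": t, "tp": tp, "fp": fp, "fn": fn}
        for t, (tp, fp, fn) in VALIDATION_COUNTS.items()
    ]
    return pd.DataFrame(rows)


def _histogram(counts_below: list[int], total: int, thresholds: list[float]) -> list[float]:
    """Expand cumulative at-or-below counts into per-day representative values.

    Days between consecutive thresholds get the upper (less negative)
    threshold as value — on the inclusive (<=) alert rule that value alerts
    at exactly the thresholds the cumulative counts say it should.
    """
    values: list[float] = []
    values += [0.0] * (total - counts_below[0])          # above the mildest threshold
    for upper, n_upper, n_lower in zip(thresholds, counts_below, counts_below[1:]):
        values += [upper] * (n_upper - n_lower)
    values += [thresholds[-1]] * counts_below[-1]        # at or below the deepest
    assert len(values) == total
    return values


def reconstruct_validation_days(
    foal_date: str = "2021-03-31",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A 147-day daily STd-6h table + events consistent with the printed sweep.

    Returns
    -------
    (std6h_days, events)
        ``std6h_days`` in the schema of
        :func:`foalwatch.preprocess.std6h_daily` (all days evaluable,
        ``n_diffs=12``): 22 mares foaling the same night, 15 with 7-day and
        7 with 6-day windows (147 days, mean 6.68 — the printed 5-7 day
        range and 6.7 mean); ``events`` places every foaling at 23:00 of
        ``foal_date``.  Day-level values are representative of their
        between-threshold bin, so every confusion count of the printed
        sweep is reproduced exactly; within-bin placement is not knowable
        from the published counts.
    """
    thresholds = sorted(VALIDATION_COUNTS, reverse=True)
    tp = [VALIDATION_COUNTS[t][0] for t in thresholds]
    fp = [VALIDATION_COUNTS[t][1] for t in thresholds]
    foal_values = _histogram(tp, N_FOALING_DAYS, thresholds)
    nonfoal_values = _histogram(fp, N_VALIDATION_DAYS - N_FOALING_DAYS, thresholds)

    foal_day = pd.Timestamp(foal_date)
    eval_clock = pd.Timedelta(hours=15)
    window_days = [7] * 15 + [6] * 7          # 15*7 + 7*6 = 147
    assert sum(window_days) == N_VALIDATION_DAYS

    rows = []
    events = []
    nonfoal_iter = iter(nonfoal_values)
    for i, n_days in enumerate(window_days):
        mare = f"m{i + 1:02d}"
        for back in range(n_days - 1, 0, -1):
            rows.append(
                {
                    "mare_id": mare,
                    "eval_time": foal_day - pd.Timedelta(days=back) + eval_clock,
                    "std6h": next(nonfoal_iter),
                    "n_diffs": 12,
                    "evaluable": True,
                }
            )
        rows.append(
            {
                "mare_id": mare,
                "eval_time": foal_day + eval_clock,
                "std6h": foal_values[i],
                "n_diffs": 12,
                "evaluable": True,
            }
        )
        events.append(
            {"mare_id": mare, "foaling_time": foal_day + pd.Timedelta(hours=23)}
        )
    std6h_days = pd.DataFrame(rows)
    events_df = pd.DataFrame(events)
    events_df["foaling_time"] = pd.to_datetime(events_df["foaling_time"])
    return std6h_days, events_df
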