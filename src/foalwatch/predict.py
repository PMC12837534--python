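"""Threshold alerting: turn daily STd-6h values into nocturnal-foaling alerts.

The decision rule is deliberately simple — a hard threshold, no score or
calibration: an evaluable day raises a positive alert when its STd-6h lies
at or below a (negative) threshold in °C.  The comparison is inclusive
(``<=``) because the statistic is built from 0.05 °C-quantized readings and
can tie a grid threshold exactly; an exclusive variant is exposed via
``inclusive=False``.  The default threshold grid spans -0.05 to -0.55 °C in
0.05 °C steps, the sweep used by the day-level validation harness.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["DEFAULT_THRESHOLDS", "threshold_grid", "classify_day", "sweep"]

#: Default alert-threshold sweep, °C (strictly decreasing, all negative).
DEFAULT_THRESHOLDS: tuple[float, ...] = tuple(
    round(-0.05 * k, 2) for k in range(1, 12)
)


def threshold_grid(
    start: float = -0.05, stop: float = -0.55, step: float = -0.05
) -> tuple[float, ...]:
    """Build a strictly decreasing grid of negative thresholds (inclusive of ``stop``)."""
    if step >= 0 or start >= 0:
        raise ValueError("thresholds must be negative and the grid decreasing")
    n = int(round((stop - start) / step)) + 1
    grid = tuple(round(start + k * step, 10) for k in range(n))
    _validate_grid(grid)
    return grid


def _validate_grid(grid: tuple[float, ...]) -> None:
    if not grid:
        raise ValueError("threshold grid is empty")
    if any(t >= 0 for t in grid):
        raise ValueError(f"all thresholds must be negative, got {grid}")
    if any(b >= a for a, b in zip(grid, grid[1:])):
        raise ValueError(f"threshold grid must be strictly decreasing, got {grid}")


def classify_day(
    std6h: float,
    threshold: float,
    evaluable: bool = True,
    inclusive: bool = True,
) -> bool:
    """Alert decision for one mare-day.

    True iff the day is evaluable and ``std6h <= threshold`` (``<`` when
    ``inclusive=False``).  Non-evaluable days never alert.
    """
    if threshold >= 0:
        raise ValueError(f"alert threshold must be negative, got {threshold}")
    if not evaluable or pd.isna(std6h):
        return False
    return std6h <= threshold if inclusive else std6h < threshold


def sweep(
    std6h_days: pd.DataFrame,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    inclusive: bool = True,
) -> pd.DataFrame:
    """Cross every mare-day with every threshold of the grid.

    Parameters
    ----------
    std6h_days
        Daily statistic table (``mare_id, eval_time, std6h, n_diffs,
        evaluable``) as produced by :func:`foalwatch.preprocess.std6h_daily`.
    thresholds
        Strictly decreasing negative grid.

    Returns
    -------
    DataFrame ``mare_id, eval_date, threshold, std6h, evaluable, alert``;
    non-evaluable days are kept (``alert=False``) so that they can be
    reported distinctly rather than silently counted as negatives.
    """
    _validate_grid(tuple(thresholds))
    if std6h_days.empty:
        return pd.DataFrame(
            columns=["mare_id", "eval_date", "threshold", "std6h", "evaluable", "alert"]
        )
    days = std6h_days.assign(eval_date=std6h_days["eval_time"].dt.normalize())
    out = days[["mare_id", "eval_date", "std6h", "evaluable"]].merge(
        pd.DataFrame({"threshold": list(thresholds)}), how="cross"
    )
    value = out["std6h"].to_numpy(dtype=float)
    thr = out["threshold"].to_numpy(dtype=float)
    hit = value <= thr if inclusive else value < thr  # NaN compares False
    out["alert"] = out["evaluable"].to_numpy(dtype=bool) & hit
    return out[["mare_id", "eval_date", "threshold", "std6h", "evaluable", "alert"]]
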