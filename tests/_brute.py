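"""Independent brute-force recomputation of the STd-6h chain.

Deliberately written with plain-python dicts and loops (no pandas, no code
shared with the package) so it can serve as an oracle for the vectorised
pipeline.
"""

from __future__ import annotations

from datetime import datetime, timedelta


def brute_hourly_max(rows: list[tuple[str, datetime, float]]) -> dict:
    """(mare, hour-bin-start) -> max temperature, from raw record triples."""
    out: dict[tuple[str, datetime], float] = {}
    for mare, ts, temp in rows:
        bin_start = ts.replace(minute=0, second=0, microsecond=0)
        key = (mare, bin_start)
        if key not in out or temp > out[key]:
            out[key] = temp
    return out


def brute_std6h(
    rows: list[tuple[str, datetime, float]],
    mare: str,
    eval_time: datetime,
    window_h: int = 6,
    min_coverage: int = 12,
) -> tuple[float | None, int]:
    """(STd-6h value or None, n_diffs) for one mare at one instant."""
    maxes = brute_hourly_max(rows)
    diffs: list[float] = []
    for k in range(1, window_h + 1):
        b = eval_time - timedelta(hours=k)
        cur = maxes.get((mare, b))
        if cur is None:
            continue
        for lag_days in (1, 2):
            prev = maxes.get((mare, b - timedelta(days=lag_days)))
            if prev is not None:
                diffs.append(cur - prev)
    if len(diffs) < min_coverage:
        return None, len(diffs)
    return sum(diffs) / len(diffs), len(diffs)
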