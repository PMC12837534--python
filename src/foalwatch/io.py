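"""Reading, validation and writing of tail-sensor temperature streams.

The on-disk interchange formats are deliberately plain:

* **sensor CSV** — one row per transmitted reading, header row, columns for
  mare identifier, ISO-8601 local timestamp and temperature in decimal °C
  (default column names ``mare_id,timestamp,temp_c``, remappable);
* **events CSV** — one row per foaling, columns ``mare_id,foaling_time``;
* **output tables** — TSV, UTF-8, ``.`` decimal separator.

Validation enforces the physical contract of the tail sensor: readings
outside its 20–45 °C operating range are *dropped* (a reading outside the
range is a transmission or exposure fault, not data), duplicate timestamps
are resolved last-read-wins (retransmission semantics), and per-mare
timestamps are strictly increasing afterwards.  Timestamps are naive local
wall-clock times; the study region observes no daylight-saving shifts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "SENSOR_RANGE_C",
    "SENSOR_COLUMNS",
    "EVENT_COLUMNS",
    "Cohort",
    "validate_sensor_frame",
    "read_sensor_csv",
    "read_events_csv",
    "write_table",
    "read_table",
]

log = logging.getLogger(__name__)

#: Operating range of the tail thermistor, °C.  Readings outside are faults.
SENSOR_RANGE_C = (20.0, 45.0)

#: Default column names of a sensor CSV.
SENSOR_COLUMNS = ("mare_id", "timestamp", "temp_c")

#: Default column names of a foaling-event CSV.
EVENT_COLUMNS = ("mare_id", "foaling_time")


@dataclass
class Cohort:
    """A monitored group of mares: validated records plus foaling events.

    Parameters
    ----------
    records
        Validated sensor readings, columns ``mare_id, timestamp, temp_c``,
        sorted by mare then timestamp, strictly increasing per mare.
    events
        Foaling events, columns ``mare_id, foaling_time``; at most one row
        per mare.  Mares without an event are allowed (ongoing monitoring).
    provenance
        Free-text source tag (file path, simulator seed, ...).
    """

    records: pd.DataFrame
    events: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        known = set(self.records["mare_id"].unique())
        orphan = set(self.events["mare_id"]) - known
        if orphan:
            raise ValueError(
                f"foaling events refer to mares with no sensor records: {sorted(orphan)}"
            )

    @property
    def mare_ids(self) -> list[str]:
        return sorted(self.records["mare_id"].unique())


def _resolve_columns(
    df: pd.DataFrame, wanted: tuple[str, ...], dialect: Mapping[str, str] | None
) -> pd.DataFrame:
    """Rename dialect columns to canonical names; fail naming any missing column."""
    mapping = {name: name for name in wanted}
    if dialect:
        mapping.update({k: v for k, v in dialect.items() if k in wanted})
    missing = [src for src in mapping.values() if src not in df.columns]
    if missing:
        raise ValueError(f"required column(s) missing from input: {missing}")
    return df.rename(columns={src: dst for dst, src in mapping.items()})[list(wanted)]


def validate_sensor_frame(
    df: pd.DataFrame,
    lo: float = SENSOR_RANGE_C[0],
    hi: float = SENSOR_RANGE_C[1],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate a raw sensor frame against the sensor's physical contract.

    Applies, in order: timestamp/temperature parsing (unparseable rows are
    rejected), the [lo, hi] operating-range filter (out-of-range readings are
    dropped, never clamped), duplicate-timestamp resolution (last read wins)
    and per-mare chronological sorting.

    Returns
    -------
    (clean, drops)
        ``clean`` — validated records; ``drops`` — one row per
        ``(mare_id, reason)`` with the count of rejected records, reasons in
        ``{"bad_timestamp", "bad_temperature", "out_of_range",
        "duplicate_timestamp"}``.
    """
    work = df.copy()
    work["mare_id"] = work["mare_id"].astype(str)
    if pd.api.types.is_datetime64_any_dtype(work["timestamp"]):
        ts = work["timestamp"]
    else:
        ts = pd.to_datetime(work["timestamp"], errors="coerce", format="ISO8601")
    temp = pd.to_numeric(work["temp_c"], errors="coerce")

    drops: list[pd.DataFrame] = []

    def _log_drop(mask: pd.Series, reason: str) -> None:
        if mask.any():
            counts = (
                work.loc[mask, "mare_id"].value_counts().rename_axis("mare_id")
                .reset_index(name="n_dropped")
            )
            counts.insert(1, "reason", reason)
            drops.append(counts)
            for _, row in counts.iterrows():
                log.debug(
                    "dropped %d record(s) for mare %s: %s",
                    row["n_dropped"], row["mare_id"], reason,
                )

    bad_ts = ts.isna()
    _log_drop(bad_ts, "bad_timestamp")
    bad_temp = ~bad_ts & temp.isna()
    _log_drop(bad_temp, "bad_temperature")
    out_of_range = ~bad_ts & ~bad_temp & ((temp < lo) | (temp > hi))
    _log_drop(out_of_range, "out_of_range")

    keep = ~(bad_ts | bad_temp | out_of_range)
    clean = pd.DataFrame(
        {"mare_id": work.loc[keep, "mare_id"], "timestamp": ts[keep], "temp_c": temp[keep]}
    )
    # Stable sort preserves arrival order within a timestamp so that
    # keep="last" implements last-read-wins for retransmitted packets.
    clean = clean.sort_values(["mare_id", "timestamp"], kind="stable")
    dup = clean.duplicated(["mare_id", "timestamp"], keep="last")
    if dup.any():
        counts = (
            clean.loc[dup, "mare_id"].value_counts().rename_axis("mare_id")
            .reset_index(name="n_dropped")
        )
        counts.insert(1, "reason", "duplicate_timestamp")
        drops.append(counts)
    clean = clean[~dup].reset_index(drop=True)

    drop_frame = (
        pd.concat(drops, ignore_index=True)
        if drops
        else pd.DataFrame(columns=["mare_id", "reason", "n_dropped"])
    )
    return clean, drop_frame


def read_sensor_csv(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a sensor CSV.

    Parameters
    ----------
    path
        CSV file with a header row.
    dialect
        Optional map from canonical names (``mare_id``, ``timestamp``,
        ``temp_c``) to the column names actually present in the file.

    Returns
    -------
    (records, drops)
        Validated records and the per-mare drop log of
        :func:`validate_sensor_frame`.
    """
    raw = pd.read_csv(path, dtype=str)
    raw = _resolve_columns(raw, SENSOR_COLUMNS, dialect)
    return validate_sensor_frame(raw)


def read_events_csv(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a foaling-event CSV (``mare_id, foaling_time``).

    Mares absent from the file are simply unfoaled; a duplicated ``mare_id``
    or an unparseable foaling time is a hard error — the event table is the
    ground truth of the validation and must not be silently repaired.
    """
    raw = pd.read_csv(path, dtype=str)
    raw = _resolve_columns(raw, EVENT_COLUMNS, dialect)
    events = pd.DataFrame(
        {
            "mare_id": raw["mare_id"].astype(str),
            "foaling_time": pd.to_datetime(
                raw["foaling_time"], errors="coerce", format="ISO8601"
            ),
        }
    )
    if events["foaling_time"].isna().any():
        bad = events.loc[events["foaling_time"].isna(), "mare_id"].tolist()
        raise ValueError(f"unparseable foaling_time for mare(s): {bad}")
    dup = events["mare_id"][events["mare_id"].duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate foaling event for mare(s): {dup}")
    return events.reset_index(drop=True)


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV (UTF-8, '.' decimal, deterministic columns)."""
    if rows is None:
        raise ValueError("rows must not be None")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    rows.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table` (datetimes re-parsed lazily by caller)."""
    return pd.read_csv(path, sep="\t")
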