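"""Synthetic VTB-ST cohort generator.

Emulates exactly the statistical structure the alert pipeline consumes —
no thermoregulatory physiology, just the signal anatomy of a tail-mounted
skin thermistor on a prepartum mare:

* a circadian baseline ``midline + amp * cos(2*pi*(t - peak_time)/24 h)``
  with an evening peak (default 19:30) and early-morning trough;
* a prepartum decline that ramps linearly from ``drop_onset_h_before_foaling``
  hours before foaling over ``drop_ramp_h`` hours and then holds at
  ``drop_magnitude_c`` until delivery — the gradual drop completed well
  before parturition, not a terminal plunge;
* a constant per-mare sensor bias (the device's absolute accuracy);
  day-over-day differencing cancels it, which is testable;
* Poisson-placed transient *cooling artifacts* (lying, tail raising,
  rain/snow): each excursion descends linearly to a random depth over its
  duration and recovers instantly when contact is restored;
* Gaussian read noise, 0.05 °C quantization, and the 20-45 °C sensor
  range (out-of-range values are transmitted as silence, i.e. absent).

Foaling times are drawn uniformly inside the night window [18:00, 06:00)
of the last simulated day; recording stops at delivery (the device is
removed).  Everything is reproducible from ``SynthConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import datetime, time

import numpy as np
import pandas as pd

from .io import SENSOR_RANGE_C, Cohort

__all__ = ["SynthConfig", "SynthCohort", "baseline", "quantize_clamp", "generate_cohort"]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic cohort; defaults encode the study conditions."""

    n_mares: int = 22
    days: int = 10                      # recording span; foaling on the last night
    sample_interval_min: float = 3.0    # transmission cadence, minutes
    start: datetime = datetime(2024, 3, 1)
    midline_c: float = 36.85            # circadian midline, °C
    circadian_amp_c: float = 0.25       # circadian half-amplitude, °C
    peak_time: time = time(19, 30)      # clock time of the circadian maximum
    drop_magnitude_c: float = 0.25      # prepartum decline depth, °C
    drop_onset_h_before_foaling: float = 36.0   # decline starts this long before foaling
    drop_ramp_h: float = 18.0           # hours from onset to full depth (then plateau)
    night_window: tuple[time, time] = (time(18, 0), time(6, 0))
    artifact_rate_per_h: float = 0.5    # expected cooling excursions per hour
    artifact_depth_c: tuple[float, float] = (1.0, 10.0)   # uniform depth range, °C
    artifact_len_min: tuple[float, float] = (3.0, 45.0)   # uniform duration range, min
    noise_sd_c: float = 0.08            # per-sample Gaussian read noise, °C
    sensor_bias_c: float = 0.3          # per-mare constant offset ~ U(-bias, +bias), °C
    resolution_c: float = 0.05          # sensor quantization step, °C
    foal: bool = True                   # emit a foaling event per mare
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "n_mares": self.n_mares, "days": self.days,
            "sample_interval_min": self.sample_interval_min,
            "resolution_c": self.resolution_c,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"SynthConfig.{name} must be positive, got {value}")
        if self.sample_interval_min < 1:
            raise ValueError("SynthConfig.sample_interval_min must be >= 1 minute")
        nonneg = {
            "circadian_amp_c": self.circadian_amp_c,
            "drop_magnitude_c": self.drop_magnitude_c,
            "drop_onset_h_before_foaling": self.drop_onset_h_before_foaling,
            "drop_ramp_h": self.drop_ramp_h,
            "artifact_rate_per_h": self.artifact_rate_per_h,
            "noise_sd_c": self.noise_sd_c,
            "sensor_bias_c": self.sensor_bias_c,
        }
        for name, value in nonneg.items():
            if value < 0:
                raise ValueError(f"SynthConfig.{name} must be >= 0, got {value}")

    def with_(self, **changes) -> "SynthConfig":
        """A copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass
class SynthCohort:
    """A generated cohort plus its injected ground truth.

    ``truth`` has one row per mare: foaling time, injected drop magnitude,
    and the constant sensor bias — the oracle for parameter-recovery tests.
    """

    cohort: Cohort
    truth: pd.DataFrame
    config: SynthConfig


def _clock_hours(t: time) -> float:
    return t.hour + t.minute / 60.0 + t.second / 3600.0


def baseline(t: pd.Timestamp | np.ndarray, cfg: SynthConfig) -> float | np.ndarray:
    """Deterministic circadian baseline at wall-clock instant(s) ``t``, °C."""
    if isinstance(t, (pd.Timestamp, datetime)):
        ts = pd.Timestamp(t)
        hours = np.array([(ts - ts.normalize()) / pd.Timedelta(hours=1)])
        scalar = True
    else:
        hours = np.asarray(t, dtype=float)
        scalar = False
    phase = 2.0 * np.pi * (hours - _clock_hours(cfg.peak_time)) / 24.0
    value = cfg.midline_c + cfg.circadian_amp_c * np.cos(phase)
    return float(value[0]) if scalar else value


def quantize_clamp(
    x: np.ndarray | float,
    resolution: float = 0.05,
    lo: float = SENSOR_RANGE_C[0],
    hi: float = SENSOR_RANGE_C[1],
) -> np.ndarray:
    """Quantize to the sensor grid (half-up) and blank out-of-range values.

    Returns an array with NaN where the true value lies outside ``[lo, hi]``
    — the sensor transmits nothing there (silence), it never clamps.
    """
    if resolution <= 0:
        raise ValueError(f"resolution must be positive, got {resolution}")
    arr = np.asarray(x, dtype=float)
    # Half-up on the resolution grid; the epsilon absorbs binary-float slop
    # so that e.g. 36.875 reliably rounds to 36.90.
    q = np.floor(arr / resolution + 0.5 + 1e-9) * resolution
    q = np.round(q, 6)
    out = np.where((arr < lo) | (arr > hi), np.nan, q)
    return out


def _artifact_depression(
    t_min: np.ndarray, span_min: float, cfg: SynthConfig, rng: np.random.Generator
) -> np.ndarray:
    """Downward excursion depth at each sample time (minutes from start)."""
    depression = np.zeros_like(t_min)
    n = rng.poisson(cfg.artifact_rate_per_h * span_min / 60.0)
    if n == 0:
        return depression
    starts = rng.uniform(0.0, span_min, size=n)
    lengths = rng.uniform(*cfg.artifact_len_min, size=n)
    depths = rng.uniform(*cfg.artifact_depth_c, size=n)
    for a, length, depth in zip(starts, lengths, depths):
        in_dip = (t_min >= a) & (t_min < a + length)
        if in_dip.any():
            # Linear cooling towards the dip's depth; instant rewarming at
            # the end (the horse stands up / contact is restored).
            frac = (t_min[in_dip] - a) / length
            np.maximum.at(depression, np.nonzero(in_dip)[0], depth * frac)
    return depression


def generate_cohort(cfg: SynthConfig) -> SynthCohort:
    """Generate a reproducible synthetic cohort under ``cfg``.

    Per mare: circadian baseline + prepartum decline + constant bias +
    Gaussian noise - cooling artifacts, then sensor quantization and the
    operating-range filter.  Records satisfy the ingest validation by
    construction (sorted, strictly increasing timestamps, in-range).
    """
    rng = np.random.default_rng(cfg.seed)
    start = pd.Timestamp(cfg.start).normalize()
    night_start, night_end = cfg.night_window
    night_len_h = (24.0 - _clock_hours(night_start)) + _clock_hours(night_end)

    record_frames = []
    events = []
    truth_rows = []
    width = len(str(cfg.n_mares))
    for i in range(cfg.n_mares):
        mare = f"m{i + 1:0{width}d}"
        bias = rng.uniform(-cfg.sensor_bias_c, cfg.sensor_bias_c)

        if cfg.foal:
            offset_h = rng.uniform(0.0, night_len_h)
            foal_time = (
                start
                + pd.Timedelta(days=cfg.days - 1)
                + pd.Timedelta(hours=_clock_hours(night_start) + offset_h)
            ).floor("min")  # delivery times are recorded to the minute
            end = foal_time
        else:
            foal_time = pd.NaT
            end = start + pd.Timedelta(days=cfg.days)

        step = pd.Timedelta(minutes=cfg.sample_interval_min)
        times = pd.date_range(start, end, freq=step, inclusive="left")
        rel_h = (times - start) / pd.Timedelta(hours=1)
        clock_h = np.asarray(rel_h) % 24.0

        temp = baseline(clock_h, cfg) + bias
        if cfg.foal and cfg.drop_magnitude_c > 0:
            h_before = (foal_time - times) / pd.Timedelta(hours=1)
            if cfg.drop_ramp_h > 0:
                frac = (cfg.drop_onset_h_before_foaling - np.asarray(h_before)) / cfg.drop_ramp_h
                frac = np.clip(frac, 0.0, 1.0)
            else:
                frac = (np.asarray(h_before) <= cfg.drop_onset_h_before_foaling).astype(float)
            temp = temp - cfg.drop_magnitude_c * frac
        temp = temp + rng.normal(0.0, cfg.noise_sd_c, size=temp.size)
        span_min = float(np.asarray(rel_h)[-1] * 60.0) if len(times) else 0.0
        temp = temp - _artifact_depression(
            np.asarray(rel_h) * 60.0, span_min, cfg, rng
        )

        quantized = quantize_clamp(temp, cfg.resolution_c)
        keep = ~np.isnan(quantized)
        record_frames.append(
            pd.DataFrame(
                {"mare_id": mare, "timestamp": times[keep], "temp_c": quantized[keep]}
            )
        )
        if cfg.foal:
            events.append({"mare_id": mare, "foaling_time": foal_time})
        truth_rows.append(
            {
                "mare_id": mare,
                "foaling_time": foal_time,
                "drop_magnitude_c": cfg.drop_magnitude_c if cfg.foal else 0.0,
                "sensor_bias_c": bias,
            }
        )

    records = pd.concat(record_frames, ignore_index=True)
    events_df = pd.DataFrame(events, columns=["mare_id", "foaling_time"])
    cohort = Cohort(records=records, events=events_df, provenance=f"synthetic(seed={cfg.seed})")
    return SynthCohort(cohort=cohort, truth=pd.DataFrame(truth_rows), config=cfg)
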