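# Methods

## The problem and the signal

Most mares foal at night, gestation length is highly variable, and an
unattended foaling carries a markedly higher risk of losing the foal.  A
thermistor pressed between the ventral tail base and the anus records a
skin temperature (VTB-ST) that tracks core temperature closely, and body
temperature declines gradually in the one to two days before parturition.
`foalwatch` turns that stream into a once-daily yes/no alert: *will this
mare foal tonight (18:00–06:00)?*

Two features of the raw stream drive the design.  First, VTB-ST has a clear
circadian rhythm (evening maximum around 36.9–37.2 °C, early-morning
minimum around 36.5–36.7 °C), larger than the prepartum decline itself, so
absolute temperatures are useless without baseline removal.  Second, the
sensor reads spuriously *low* — never high — whenever colder outside air
reaches it (lying bouts, tail raising, rain, snow), so robust aggregation
must be one-sided.

## The statistic

For each mare:

1. **Hourly maximum.**  `M(d, h)` = the highest validated reading in the
   clock-hour bin `[h:00, h+1:00)` of day `d`.  Because artifacts are
   strictly downward excursions, the maximum recovers the undisturbed
   temperature whenever at least one clean sample lands in the hour.  Bins
   with no readings stay missing; nothing is interpolated.
2. **Day differences.**  `STd1(d,h) = M(d,h) − M(d−1,h)` and
   `STd2(d,h) = M(d,h) − M(d−2,h)`, each defined only when both operands
   exist.  Differencing at the same clock hour removes the circadian
   baseline and any constant per-device bias.  Two lags make the statistic
   less sensitive to a single anomalous reference day.
3. **STd-6h.**  At the daily evaluation instant (15:00), the unweighted
   mean of all STd1 and STd2 values from the six hour-bins
   `[09:00, 15:00)` — up to 12 values.  The 9:00–15:00 window is the
   daytime period least affected by husbandry differences between farms
   (prepartum mares elsewhere are typically stabled at night), which is
   what makes the rule portable.

A day is *evaluable* only when at least `min_coverage` of the 12 possible
differences exist.  The default is 12 (strict completeness), matching a
validation design that required seven consecutive days of data; a softer
setting is exposed for field use where occasional dropout is normal.

**Alert rule.**  Alert iff the day is evaluable and `STd-6h ≤ θ` for a
negative threshold θ.  The comparison is inclusive because the 0.05 °C
input quantization can tie θ exactly; `alert_inclusive=False` gives the
strict variant.  The evaluation sweeps θ over −0.05 … −0.55 °C in 0.05 °C
steps; no probabilistic score is attached — the published rule is a hard
threshold and the package reproduces exactly that.

## Day-level scoring

The night window of evaluation day `D` is `[D 18:00, D+1 06:00)` —
half-open, so a delivery at exactly 06:00 counts as daytime; post-midnight
births are credited to the preceding evaluation date (the 15:00 evaluation
that could have predicted them).  Daytime-foaling mares are excluded with a
logged reason, as are mares whose foaling day is not evaluable.

Per mare the validation window is the foaling day plus up to six preceding
*consecutive* evaluable days (≤ 7 total); mares with fewer than five are
excluded.  Capping the window matters: with a fixed per-mare day budget the
number of negatives — and hence precision and alerts-per-mare — is
well-defined and comparable.  TP/FP/FN, sensitivity and precision follow
the standard formulas; percentages are rounded half-up to one decimal
(`decimal.Decimal`, not float `round`, so ties never round down).  True
negatives and specificity are computed (`include_negatives=True`) but kept
out of the headline table: negatives dominate by construction and
specificity mostly measures the window length.

Descriptive summaries use 24-h periods anchored at the daily 15:00
preceding foaling (so no post-15:00 parturition-day data enter), pooled
across mares, with 3-h sub-bins and linear-interpolation percentiles.

## The reconstructed validation fixture

The published field validation (22 night-foaling heavy draft mares, 147
mare-days, 5–7-day windows averaging 6.7) printed cumulative TP and FP
counts per threshold.  Differencing consecutive entries yields the exact
histogram of day-level STd-6h values over the grid;
`reference.reconstruct_validation_days` materialises one consistent
day-level data set (15 mares × 7 days + 7 mares × 6 days; each day's value
set to its bin's upper threshold, which is faithful at grid resolution —
within-bin placement is unknowable from the counts).  Running the full
predictor + evaluator over this fixture must reproduce every printed row
exactly; the test suite and `scripts/acceptance.py` do so.  What this does
*not* test is the preprocessing chain on real sensor data — that is covered
separately by the brute-force oracle and the simulator.

## The synthetic cohort generator

The generator emulates the statistics the algorithm consumes, not
thermoregulatory physiology.  Per mare, the true temperature is

```
T(t) = midline + amp·cos(2π (t − peak)/24 h)   circadian baseline
     − drop(t)                                  prepartum decline
     + bias                                     per-device accuracy offset
     + ε(t)                                     Gaussian read noise
     − artifact(t)                              cooling excursions
```

then quantized to the 0.05 °C grid (half-up) and blanked outside the
20–45 °C range (sensor silence, not clamping).  Defaults, with rationale:

| parameter | default | why |
|---|---|---|
| `midline_c` / `circadian_amp_c` | 36.85 / 0.25 °C | places the pooled 3-h medians at ~37.05 (evening) and ~36.6 (early morning), inside the observed 36.9–37.2 and 36.5–36.7 °C ranges |
| `peak_time` | 19:30 | evening maximum between 18:00 and 21:00 |
| `drop_magnitude_c` | 0.25 °C | observed −1d median sits ~0.2 °C below the preceding days; reported declines are 0.2–0.3 °C |
| `drop_onset_h_before_foaling` / `drop_ramp_h` | 36 h / 18 h | the decline happens *gradually, completing well before delivery*: a linear ramp from 36 h to 18 h before foaling, then a plateau.  This reproduces both the −1d daily-median shift (~−0.2 °C) and a near-full-depth STd-6h on the foaling day.  A ramp that only reaches full depth at delivery cannot do either, because the 15:00 evaluation precedes foaling by 3–15 h |
| `artifact_rate_per_h`, `artifact_depth_c`, `artifact_len_min` | 0.5/h, 1–10 °C, 3–45 min | frequent, deep, short downward excursions; each descends linearly to its depth and recovers instantly (the horse stands, contact is restored), so samples near an excursion's start are barely depressed |
| `noise_sd_c` | 0.08 °C | read noise on the same order as the quantization step |
| `sensor_bias_c` | ±0.3 °C per-mare constant | the device's stated absolute accuracy modelled as bias, not per-sample noise — day differences cancel a constant offset, and a test asserts exactly that |
| `sample_interval_min` | 3 | transmission cadence; no algorithm step assumes it |
| foaling time | uniform in [18:00, 06:00) of the last night | nocturnal-validation population |

What the generator deliberately does **not** model: seasonal/ambient
temperature effects on the prepartum pattern, upward artifacts (none are
plausible for a cooling mechanism), belt slippage or battery decay,
correlated multi-day dropout, daytime foalings, and individual variation in
decline shape.  Passing the synthetic tests therefore shows the pipeline
recovers the signal it was designed for under realistic noise and artifact
load — it does not show field-accuracy numbers transfer to other farms,
breeds or seasons, which the original study itself flags as open.

## Numerical choices and degenerate inputs

* Hour bins and windows are half-open everywhere (`[9,15)` window,
  `[18:00, 06:00)` night); a reading exactly at 15:00 belongs to the next
  window.
* STd-6h pools up to 12 differences and takes one mean (identical to the
  mean of the two 6-bin means when complete; the pooled form is the
  declared behaviour when incomplete).
* Ingest validation: out-of-range readings dropped (never clamped),
  duplicate timestamps resolved last-read-wins, rows with unparseable
  fields rejected with a per-mare logged count; a missing required column
  is a hard error naming the column.
* Sensor quantization uses floor(x/res + 0.5 + 1e−9): half-up with an
  epsilon absorbing binary-float slop at ties.
* Empty inputs propagate as empty outputs (never exceptions) everywhere
  except explicit contract violations (non-negative thresholds, zero-width
  windows, duplicated events), which raise `ValueError` naming the field.
* Statistics with zero denominators are reported absent (NaN), never 0.

## Problem sizes in tests

The test suite and acceptance script use cohorts scaled to what the checks
need: 1–2-mare, 4–5-day cohorts at 15–30-min cadence for the 100-cohort
brute-force oracle comparison; a 50-mare, 10-day cohort at the nominal
3-min cadence for drop recovery; the default 22-mare cohort for circadian
calibration.  These sizes give stable statistics (oracle agreement is
exact; recovery rates are ~10 percentage points away from their bounds)
while keeping a full run in seconds.

## Known limitations

* The evaluation-time/window defaults encode one husbandry pattern
  (daytime paddock, 15:00 evaluation); other protocols need re-validation,
  not just re-configuration.
* `min_coverage=12` is strict: a single missing hour bin in any of three
  days silently makes a day non-evaluable.  The pipeline reports these
  days distinctly, but operationally they are missed evaluation
  opportunities.
* The reconstructed fixture pins day-level behaviour to the published
  counts but cannot validate the preprocessing chain against the original
  raw data; `evaluation.circadian_summary` and
  `evaluation.std6h_distribution` accept any real cohort CSV for that
  purpose.
* Within the night window the alert carries no timing information; it
  predicts *that* night, not *when* during it.
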