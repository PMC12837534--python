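# foalwatch

Nocturnal-foaling prediction for mares from ventral tail-base surface
temperature (VTB-ST), recorded by a tail-attached wearable thermistor.

Most mares foal at night, and an unattended foaling sharply raises the risk
of losing the foal.  Body temperature declines gradually in the last one to
two days of pregnancy; `foalwatch` detects that decline in a noisy,
artifact-laden skin-temperature stream and raises a once-daily alert at
15:00: *will this mare foal tonight (18:00–06:00)?*

The package is aimed at researchers in precision livestock farming and
equine reproduction who want to reproduce, stress-test or extend this class
of threshold-alert algorithm — including anyone with their own sensor CSVs.

## The statistic

For each mare, with `M(d,h)` the maximum reading in clock-hour bin `h` of
day `d` (the maximum suppresses the sensor's strictly-downward cooling
artifacts):

```
STd1(d,h) = M(d,h) − M(d−1,h)          same-hour difference, 1 day back
STd2(d,h) = M(d,h) − M(d−2,h)          same-hour difference, 2 days back
STd-6h(d) = mean of the 12 values {STd1, STd2} over h ∈ [9:00, 15:00)
```

Differencing at the same clock hour removes the circadian rhythm (which is
larger than the prepartum decline itself) and any constant sensor bias.  A
positive alert on day `d` is `STd-6h(d) ≤ θ` for a negative threshold θ
(sweep: −0.05 … −0.55 °C); the day-level harness scores it against the
following night with sensitivity = TP/(TP+FN) and precision = TP/(TP+FP).

A seeded synthetic cohort generator (circadian baseline, prepartum decline,
cooling artifacts, quantization, sensor range) makes the entire chain
testable without field data — see `docs/methods.md` for the model and its
deliberate limitations.

## Worked example

`examples/threshold_sweep.py` simulates a 20-mare cohort (10 days, foaling
on the last night, seed 1) and runs the full chain:

```
validation windows: 20 mares, 140 mare-days (20 foaling nights)

 threshold  tp  fp  fn  sensitivity  precision
     -0.05  19  14   1         95.0       57.6
     -0.10  19   3   1         95.0       86.4
     -0.15  19   3   1         95.0       86.4
     -0.20  17   3   3         85.0       85.0
     -0.25   8   1  12         40.0       88.9
     -0.30   0   1  20          0.0        0.0
     ...
```

Each row reads: at threshold −0.20 °C, 17 of the 20 foaling nights were
preceded by an alert at 15:00 (sensitivity 85.0 %), with 3 false alerts
across the 120 non-foaling days (precision 85.0 %).  Deeper thresholds
trade sensitivity for precision.  The same script prints alerts-per-mare
(the call-out cost of each threshold) and the fraction of mares at or below
−0.2 °C per day before foaling, which jumps from ≤ 10 % to 85 % on the
foaling day.

The other examples follow one mare through the preprocessing steps
(`preprocess_single_mare.py`), inspect the simulator's signal anatomy
(`simulate_cohort.py`), and reproduce the published 22-mare validation
table from its own counts (`published_validation.py`).

A thin CLI wraps the same library calls:

```
foalwatch simulate --seed 1 --n-mares 20 --days 10 --out-dir run/
foalwatch run --sensor run/sensor.csv --events run/events.csv --out-dir run/out/
```

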