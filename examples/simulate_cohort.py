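"""Generate a synthetic prepartum cohort and look at its signal anatomy.

The simulator emulates what a tail-mounted thermistor records on a mare in
the last days of pregnancy: a circadian rhythm peaking in the evening, a
gradual ~0.25 °C decline completing about a day before foaling, downward
cooling artifacts from lying / tail raising / weather, sensor noise, and
0.05 °C quantization inside the 20-45 °C operating range.
"""

import pandas as pd

from foalwatch import SynthConfig, generate_cohort

cfg = SynthConfig(n_mares=5, days=10, seed=42)
synth = generate_cohort(cfg)
records, events = synth.cohort.records, synth.cohort.events

print(f"cohort: {events.shape[0]} foaling mares, {len(records)} sensor readings")
print("\nfirst readings (3-min cadence, 0.05 °C grid):")
print(records.head(5).to_string(index=False))

print("\nfoaling times (all inside the 18:00-06:00 night window):")
print(events.to_string(index=False))

by_hour = (
    records.assign(clock=records["timestamp"].dt.hour)
    .groupby("clock")["temp_c"].median()
)
print("\nmedian temperature by clock hour (circadian rhythm, evening peak):")
print(by_hour.round(2).to_string())
print(
    "\nThe evening hours sit ~0.5 °C above the early morning; the foaling-day"
    "\ndecline and the cooling artifacts ride on top of this rhythm."
)
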