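"""Full pipeline on a synthetic cohort: simulate -> preprocess -> sweep -> score.

Runs the complete chain on a 20-mare cohort and prints the day-level
confusion table over the -0.05..-0.55 °C threshold grid: TP = foaling
nights preceded by an alert at 15:00, FP = alerts with no foaling that
night, FN = missed foaling nights; sensitivity = TP/(TP+FN), precision =
TP/(TP+FP), both in percent.
"""

from foalwatch import RunConfig, SynthConfig, generate_cohort, run_pipeline

synth = generate_cohort(SynthConfig(n_mares=20, days=10, seed=1))
result = run_pipeline(synth.cohort, RunConfig())

print(f"validation windows: {result.n_mares} mares, {len(result.window)} mare-days "
      f"({int(result.window['foaling_tonight'].sum())} foaling nights)\n")
print(result.confusion_table.to_string(index=False))

print("\nalerts per mare over the window (operational cost of each threshold):")
print(result.alerts_per_mare.to_string(index=False))

print("\nfraction of mares at or below -0.2 °C by day before foaling "
      "(-1 = foaling day):")
print(result.distribution.to_string(index=False))
print(
    "\nMild thresholds catch nearly every foaling night but alert often;"
    "\ndeep thresholds rarely false-alarm but miss foalings. The -0.2 to"
    "\n-0.3 °C band balances the two."
)
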