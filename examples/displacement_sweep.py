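"""Kitchen air quality across three-stone-fire displacement scenarios.

Sweeps the fraction of the 3-hr cooking day moved from the three-stone fire
to each tier stove and reports the 24-hr mean concentrations and the TSF's
share of each pollutant — the source-apportionment view that shows why
partial displacement buys so little.
"""

import numpy as np

from stovesim import DEFAULT_KITCHEN, builtin_registry, displacement_sweep

reg = builtin_registry()
tiers = [reg[t] for t in ("tier1", "tier2", "tier3", "tier4")]
df = displacement_sweep(reg["tsf"], tiers, DEFAULT_KITCHEN,
                        grid=np.array([0.0, 0.5, 1.0]))

pm = df[df.pollutant == "pm25"]
print("24-hr mean kitchen PM2.5 (ug/m3) and TSF source share")
print(f"{'new stove':<10}{'d':>6}{'PM2.5':>10}{'TSF share':>12}")
for _, row in pm.iterrows():
    print(f"{row.new_stove:<10}{row.displacement:>6.1f}"
          f"{row.mean_reporting:>10.1f}{row.baseline_share:>11.0%}")

print()
print("Reading: at 50% displacement the TSF still contributes ~98% of PM2.5")
print("even next to a tier-4 stove — only near-complete displacement with a")
print("tier-4 stove approaches the WHO targets (the d=0 baseline is 667 ug/m3).")
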