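"""How long can a traditional stove be used before WHO targets are exceeded?

Inverts the single-zone kitchen model for the daily usage time at which the
24-hr mean concentration reaches each WHO target, in the reference kitchen
(30 m3, 15 air changes per hour).
"""

from stovesim import DEFAULT_KITCHEN, builtin_registry, max_usage_minutes
from stovesim.rounding import usage_minutes

reg = builtin_registry()

print("Maximum exclusive daily use before the 24-hr mean exceeds the target")
print(f"{'stove':<22}{'target':<16}{'exact min/day':>14}{'rounded':>10}")
for stove in ("tsf", "charcoal_traditional"):
    for target in ("pm25_interim1", "pm25_final", "co_24hr"):
        t = max_usage_minutes(reg[stove], DEFAULT_KITCHEN, reg.targets[target])
        mode = "floor" if target == "co_24hr" else "nearest"
        print(f"{stove:<22}{target:<16}{t:>14.2f}{usage_minutes(t, mode):>10.0f}")

print()
print("Reading: a three-stone fire run more than ~10 min/day pushes the")
print("24-hr kitchen mean past the WHO PM2.5 interim-1 target (35 ug/m3);")
print("the CO guideline allows ~75 min/day.")
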