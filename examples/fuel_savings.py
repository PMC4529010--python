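"""Fuel savings from displacing the three-stone fire with efficient stoves.

Savings follow directly from the thermal-efficiency ratio and the
displacement fraction: savings = (1 - eta_traditional/eta_new) * d.
"""

from stovesim import (
    FuelScenario,
    UnreachableSavingsError,
    builtin_registry,
    displacement_for_savings,
    fuel_savings,
)

reg = builtin_registry()
eta_tsf = reg["tsf"].thermal_efficiency  # 15%

print("Fuel savings at full displacement of the TSF")
for tier in ("tier1", "tier2", "tier3", "tier4"):
    s = fuel_savings(FuelScenario(eta_tsf, reg[tier].thermal_efficiency, 1.0))
    print(f"  {tier} (eta {reg[tier].thermal_efficiency:.0%}): {s:.0%}")

print()
print("Displacement required for a 50% fuel-savings target")
for tier in ("tier1", "tier2", "tier3", "tier4"):
    try:
        d = displacement_for_savings(eta_tsf, reg[tier].thermal_efficiency, 0.50)
        print(f"  {tier}: d = {d:.0%}")
    except UnreachableSavingsError:
        print(f"  {tier}: unreachable even at full displacement")

print()
print("Reading: the ceiling is 70% savings (tier-4, full displacement); a")
print("50% target needs full displacement with tier 2, ~80% with tier 3, or")
print("~71% with tier 4.")
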