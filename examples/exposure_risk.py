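"""From kitchen concentrations to child exposure and ALRI relative risk.

Converts modeled 24-hr kitchen PM2.5 means to a child's exposure with the
0.628 kitchen-to-child ratio and maps exposure to relative risk through a
demonstration integrated exposure-response fit (anchored so exclusive
three-stone-fire use gives RR ~ 3 and a 75% exposure reduction gives ~2).
"""

from stovesim import (
    DEFAULT_KITCHEN,
    DisplacementScenario,
    builtin_registry,
    evaluate_scenario,
    kitchen_to_exposure,
    relative_risk,
    required_displacement,
)
from stovesim.exposure import demo_alri_parameters

reg = builtin_registry()
p = demo_alri_parameters()

print("Displacement needed for exposure-reduction goals (TSF baseline)")
for new in ("tier2", "tier3", "tier4"):
    for reduction in (0.50, 0.75):
        try:
            d = required_displacement(reg["tsf"], reg[new], DEFAULT_KITCHEN,
                                      target_reduction=reduction)
            print(f"  {new}: {reduction:.0%} exposure reduction at d = {d:.0%}")
        except ValueError as e:
            print(f"  {new}: {reduction:.0%} reduction -> {e}")

print()
print("Exposure and relative risk along tier-4 displacement")
for d in (0.0, 0.5, 0.77, 0.94, 1.0):
    res = evaluate_scenario(DisplacementScenario(reg["tsf"], reg["tier4"], d),
                            DEFAULT_KITCHEN)
    z = kitchen_to_exposure(res.mean_reporting_units("pm25"))
    print(f"  d = {d:4.0%}: exposure {z:6.1f} ug/m3, RR = {relative_risk(z, p):.2f}")

print()
print("Reading: a 75% exposure reduction (tier-3 at 86% or tier-4 at 77%")
print("displacement) moves the modeled ALRI relative risk from ~3 to ~2;")
print("even full tier-4 displacement leaves exposure ~10.5 ug/m3, above the")
print("7 ug/m3 counterfactual, hence a small residual risk.")
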