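# Methods

## The single-zone kitchen model

Indoor concentrations are modelled in one well-mixed compartment with a
constant-rate source and first-order ventilation loss. For a constant
emission rate *G* (mg/min), loss rate α = ACH/60 (per minute) and volume
*V* (m³),

    C(t) = G/(αV) · (1 − e^(−αt)) + C₀ · e^(−αt).

This is the exact solution of the mass balance `V dC/dt = G − αVC`, so the
simulator applies it as an exact per-minute update (a first-order IIR
recursion, run through `scipy.signal.lfilter`); results carry no
time-discretisation error for piecewise-constant emission schedules — the
1-minute grid is purely a reporting resolution. Assumptions inherited from
the model class: all emissions enter the room and mix instantly; ventilation
is the only loss (no deposition or coagulation); ambient/background
concentration is zero by default (a constant additive term is available but
off).

Daily means are computed from the exact analytic time integral of the
solution (per-minute closed form), not from averaging the minute samples;
this makes the ventilation mass balance

    αV·∫C dt + V·(C_end − C_start) = emitted mass

hold to machine precision, which the property suite asserts on 500 random
fixtures. The sample average agrees with the exact mean to well under 0.5%
for any schedule ending an hour before midnight, and the closed-form
shortcut `mean = G·t_on/(αV·1440)` agrees to the same tolerance because the
end-of-day decay tail at 15 ACH (α = 0.25 min⁻¹) is ~e⁻¹⁵ of the peak
within an hour of the last event.

Per-source ("source apportionment") traces are obtained by superposition:
each stove's schedule is simulated alone and the components sum to the
joint trace exactly, the model being linear in its inputs.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| kitchen volume | 30 | m³ | reference kitchen of the IWA modelling convention |
| air-exchange rate | 15 | ACH | same convention; sensitivity sweep spans 15–45 |
| cooking schedule | 3 × 60 min (07:00, 12:00, 18:00) | — | "three 1-hr events"; start times are a config knob and daily means are placement-insensitive (tested < 0.5%) |
| initial concentration | 0 | mg/m³ | single-day horizon; carryover at 15 ACH decays below 10⁻⁶ of its value within an hour |
| kitchen→child exposure ratio | 0.628 | — | empirical field ratio |
| IER counterfactual z_cf | 7 | µg/m³ | exposure below which RR = 1 |
| WHO targets | PM2.5 35 (interim-1) / 10 (final) µg/m³, CO 7 mg/m³ | 24-hr mean | guideline levels the inversions target |

Stove parameters (registry defaults): TSF 40 mg/min PM2.5, 970 mg/min CO,
η = 15% (tier 0 on every indicator); tier 1–4 representative rates are the
midpoints of the printed tier boundaries (PM 28.5/12.5/5/1, CO
795/555/455/210 mg/min — with CO tier 2 stored as printed, 555, although
the midpoint of its own printed range is 590), efficiencies 20/30/40/50%
(tier 4 extrapolated); traditional charcoal 15 mg/min PM2.5, 1300 mg/min
CO, η = 25% (an average over four common charcoal stoves).

Units: concentrations are mg/m³ internally for both pollutants; PM2.5 is
converted to µg/m³ only at reporting. Fractions (displacement, efficiency,
savings) are dimensionless internally and percent at reporting.

## Tier classification

Tier bands are stored exactly as printed, including their endpoint overlaps
(PM bands share endpoints such as 17 and 40 mg/min; CO tiers 1 and 2
overlap over 620–690 mg/min). `classify_tier` resolves any multiply-covered
value to the cleaner band — the higher tier index — a deterministic repo
convention, not something the tier tables specify. A consequence is that
the tier-0 representative values (40 mg/min PM, 970 mg/min CO, 15%
efficiency), which sit exactly on the open tier-0 boundary, classify as
tier 1; all interior representative values classify into their own tier.
Values outside every band (possible only with malformed custom bands) map
to the nearest band with a warning flag.

## Displacement convention

Displacement *d* splits every cooking event proportionally between the two
stoves. It is implemented as rate scaling — baseline emits `(1−d)·G_base`
and the new stove `d·G_new` over the full events — which by linearity gives
the same daily means, source shares and emitted mass as literal time
reallocation, while keeping each source's schedule on the minute grid for
any real-valued *d*. The schedule validator consequently forbids
overlapping segments only within a source (one stove cannot double-book);
different sources may coincide.

Total cooking time is held fixed at 3 hr/day across scenarios (adoption is
assumed not to change cooking demand); weekly-hour conversions in the
guidance matrix use the resulting 21-hr cooking week.

## Inversions and numerical choices

Both solvers use a closed form cross-checked by root finding on the
simulated model. Usage limits bisect the exact analytic daily mean
(including the end-of-day tail) with `brentq` at 0.01-min tolerance and
verify the closed form `t = level·αV·1440/G`; required displacement uses
`d = (G_base − G_goal)/(G_base − G_new)` with a simulation cross-check at
10⁻⁶ tolerance on *d*. Goals may be absolute kitchen concentrations,
absolute exposures (kitchen × ratio; the convention used for the WHO
exposure target), or fractional reductions relative to d = 0, where the
exposure ratio cancels and the kitchen and exposure scales coincide.
Degenerate cases: a goal already met at d = 0 returns 0; a goal missed even
at d = 1 raises an "unreachable" error rather than clamping. Negative fuel
savings (a less efficient "new" stove) are rejected unless explicitly
allowed.

Reported values keep full precision; a presentation formatter rounds usage
times to the nearest 5 minutes (or down to 5 minutes for the CO limit,
which is conventionally quoted as a conservative bound), fractions to whole
percent, and concentrations to 1 µg/m³.

### CO usage limits for tier stoves

A published summary ladder of "15/30/75/375 min/day before exceeding the
CO guideline" for tier 1–4 stoves is reproduced by this model only under
the PM2.5 interim-1 target with the PM emission rates; the CO rates give
roughly 95/136/166/360 min/day. `tier_usage_limits` therefore reports every
(stove, target) pair side by side rather than silently preferring either
reading.

## Exposure–response parameters

The IER curve `RR(z) = 1 + a(1 − e^(−γ(z−z_cf)^δ))` is consumed, never
fitted to epidemiological data here, and the published GBD shape-parameter
fits are not bundled: supply parameters via configuration. For examples and
tests the package ships `calibrate_ier`, which solves (a, γ) given δ so the
curve passes through two anchors; `demo_alri_parameters()` anchors
RR(418.8 µg/m³) = 3 and RR(104.7 µg/m³) = 2 — the exposure of exclusive
TSF use and a 75% reduction of it — and is labelled a demonstration fit
throughout. Absolute RR values therefore illustrate curve behaviour, not a
published epidemiological estimate. The RR machinery is endpoint-agnostic;
ALRI is simply the endpoint the demonstration anchors describe.

## Synthetic fixtures

Property tests run on fixtures sampled uniformly (seeded,
`numpy.random.default_rng`) within field-realistic bounds: 15–45 ACH,
15–60 m³, 120–280 cooking min/day (survey-based cooking-time ranges),
emission rates spanning the full tier tables (PM 0.5–45, CO 100–1300
mg/min), efficiencies 10–55%. Two stoves are drawn per fixture and ordered
so the baseline is dirtier and no more efficient, making every fixture a
valid improvement scenario. Uniform sampling is a coverage choice, not a
distributional claim: the fixtures exercise model invariants (mass balance,
linearity, inversion consistency) across the parameter box, but they do not
emulate field variability in emissions over a burn cycle, partial plume
capture, ambient infiltration, or behavioural responses — so green property
tests certify the model's internal consistency, not its fidelity to any
particular field kitchen. Degenerate (zero-width) ranges reproduce the
reference configuration exactly, which ties the fixture path to the
deterministic results.

Problem sizes: the default test-and-acceptance configuration simulates
1440-minute days; the property suites use 500 random fixtures and
40–80 hypothesis examples per invariant, sizes at which the whole suite
completes in a few seconds while exercising the full parameter box.

## Known limitations

Laboratory-derived emission rates typically understate field emissions, so
usage limits here are, if anything, generous; the single-zone assumption
conversely overstates mixing (real plumes partly escape unmixed). No
multi-household/community feedback, no ambient term by default, no burden
(PAF/DALY) calculations, and no fuel-supply accounting (energy content,
renewability). The model holds total cooking time fixed; interventions that
change cooking demand are out of scope.
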