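"""Stove performance parameters, IWA 11:2012 tier bands, and WHO air-quality targets.

The registry holds the parameter sets used throughout the package: per-stove
PM2.5 and CO indoor emission rates (mg/min) and thermal efficiencies
(fraction), the IWA indoor-emissions and efficiency tier bands with the
single representative value used for modelling each tier, and the WHO
guideline levels the scenario engine inverts against.

Tier bands are stored exactly as printed in the IWA-derived table, including
the endpoint overlaps between adjacent bands (e.g. PM 17-40 vs 8-17 share
the value 17, and CO 620-970 overlaps 490-690 over 620-690).  A value lying
in more than one band is assigned the cleaner band: the higher tier index.
For emission indicators cleaner means lower emissions; for thermal
efficiency it means higher efficiency; in both cases the printed tables
order tiers so that "cleaner" is simply the larger index, which makes the
tie-break a single rule.
"""

from __future__ import annotations

import csv
import dataclasses
import io
import json
import math
import warnings
from dataclasses import dataclass, field

import yaml

__all__ = [
    "PM25",
    "CO",
    "PM_INDOOR",
    "CO_INDOOR",
    "THERMAL_EFFICIENCY",
    "StovePerformance",
    "TierBand",
    "GuidelineTarget",
    "Registry",
    "builtin_registry",
    "classify_tier",
    "GapValueWarning",
]

# Pollutant keys used across the package.
PM25 = "pm25"
CO = "co"

# Tier indicator names.
PM_INDOOR = "pm_indoor_emissions"
CO_INDOOR = "co_indoor_emissions"
THERMAL_EFFICIENCY = "thermal_efficiency"

_INDICATORS = (PM_INDOOR, CO_INDOOR, THERMAL_EFFICIENCY)

_INDICATOR_UNITS = {
    PM_INDOOR: "mg/min",
    CO_INDOOR: "mg/min",
    THERMAL_EFFICIENCY: "fraction",
}


class GapValueWarning(UserWarning):
    """A value fell outside every printed tier band and was mapped to the nearest one."""


@dataclass(frozen=True)
class StovePerformance:
    """A stove's indoor emission rates and thermal efficiency.

    Parameters
    ----------
    name:
        Text label (e.g. ``"tsf"`` for the three-stone fire).
    pm_rate:
        PM2.5 indoor emission rate, mg/min.
    co_rate:
        CO indoor emission rate, mg/min.
    thermal_efficiency:
        Fraction of fuel energy delivered to the pot, in (0, 1].
    """

    name: str
    pm_rate: float
    co_rate: float
    thermal_efficiency: float

    def __post_init__(self) -> None:
        if not (self.pm_rate >= 0 and math.isfinite(self.pm_rate)):
            raise ValueError(f"pm_rate must be finite and >= 0, got {self.pm_rate}")
        if not (self.co_rate >= 0 and math.isfinite(self.co_rate)):
            raise ValueError(f"co_rate must be finite and >= 0, got {self.co_rate}")
        if not 0 < self.thermal_efficiency <= 1:
            raise ValueError(
                f"thermal_efficiency must be in (0, 1], got {self.thermal_efficiency}"
            )

    def emission_rate(self, pollutant: str) -> float:
        """Emission rate (mg/min) for ``pollutant`` ('pm25' or 'co')."""
        if pollutant == PM25:
            return self.pm_rate
        if pollutant == CO:
            return self.co_rate
        raise KeyError(f"unknown pollutant {pollutant!r}")


@dataclass(frozen=True)
class TierBand:
    """One tier's value range for one indicator, plus its modelling value.

    ``lower_bound``/``upper_bound`` may be ``None`` for one-sided bands
    (tier 0 emissions have no upper bound).  Bounds are treated as closed;
    shared endpoints are resolved toward the cleaner (higher-index) tier by
    :func:`classify_tier`.
    """

    indicator: str
    tier_index: int
    lower_bound: float | None
    upper_bound: float | None
    representative_value: float

    def __post_init__(self) -> None:
        if self.indicator not in _INDICATORS:
            raise ValueError(f"unknown indicator {self.indicator!r}")
        if not 0 <= self.tier_index <= 4:
            raise ValueError(f"tier_index must be 0-4, got {self.tier_index}")
        lo = -math.inf if self.lower_bound is None else self.lower_bound
        hi = math.inf if self.upper_bound is None else self.upper_bound
        if lo > hi:
            raise ValueError(f"lower_bound {lo} exceeds upper_bound {hi}")
        if self.lower_bound is not None and self.upper_bound is not None:
            if not lo <= self.representative_value <= hi:
                raise ValueError(
                    f"representative value {self.representative_value} outside "
                    f"[{lo}, {hi}] for {self.indicator} tier {self.tier_index}"
                )

    def contains(self, value: float) -> bool:
        lo = -math.inf if self.lower_bound is None else self.lower_bound
        hi = math.inf if self.upper_bound is None else self.upper_bound
        return lo <= value <= hi

    def distance(self, value: float) -> float:
        lo = -math.inf if self.lower_bound is None else self.lower_bound
        hi = math.inf if self.upper_bound is None else self.upper_bound
        if value < lo:
            return lo - value
        if value > hi:
            return value - hi
        return 0.0


@dataclass(frozen=True)
class GuidelineTarget:
    """A WHO air-quality target level.

    ``level`` is in the unit the guideline is published in: ug/m3 for PM2.5,
    mg/m3 for CO.  ``level_mg_m3`` converts to the package-internal mg/m3.
    """

    pollutant: str
    level: float
    label: str
    averaging: str = "24-hr mean"

    def __post_init__(self) -> None:
        if self.pollutant not in (PM25, CO):
            raise ValueError(f"unknown pollutant {self.pollutant!r}")
        if not self.level > 0:
            raise ValueError(f"level must be > 0, got {self.level}")

    @property
    def level_mg_m3(self) -> float:
        return self.level / 1000.0 if self.pollutant == PM25 else self.level


@dataclass
class Registry:
    """Named stoves, tier bands per indicator, and guideline targets."""

    stoves: dict[str, StovePerformance] = field(default_factory=dict)
    bands: dict[str, tuple[TierBand, ...]] = field(default_factory=dict)
    targets: dict[str, GuidelineTarget] = field(default_factory=dict)

    def __getitem__(self, name: str) -> StovePerformance:
        return self.stoves[name]

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "units": {
                "pm_rate": "mg/min",
                "co_rate": "mg/min",
                "thermal_efficiency": "fraction",
                "pm25_target": "ug/m3",
                "co_target": "mg/m3",
            },
            "stoves": {k: dataclasses.asdict(v) for k, v in self.stoves.items()},
            "bands": {
                ind: [dataclasses.asdict(b) for b in bs]
                for ind, bs in self.bands.items()
            },
            "targets": {k: dataclasses.asdict(v) for k, v in self.targets.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Registry":
        return cls(
            stoves={k: StovePerformance(**v) for k, v in d.get("stoves", {}).items()},
            bands={
                ind: tuple(TierBand(**b) for b in bs)
                for ind, bs in d.get("bands", {}).items()
            },
            targets={
                k: GuidelineTarget(**v) for k, v in d.get("targets", {}).items()
            },
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "Registry":
        return cls.from_dict(json.loads(s))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, s: str) -> "Registry":
        return cls.from_dict(yaml.safe_load(s))

    def to_csv(self) -> str:
        """Flat CSV view of the registry (stoves, bands and targets stacked)."""
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(["record", "name", "field", "value", "units"])
        for name, s in self.stoves.items():
            w.writerow(["stove", name, "pm_rate", s.pm_rate, "mg/min"])
            w.writerow(["stove", name, "co_rate", s.co_rate, "mg/min"])
            w.writerow(
                ["stove", name, "thermal_efficiency", s.thermal_efficiency, "fraction"]
            )
        for ind, bs in self.bands.items():
            for b in bs:
                u = _INDICATOR_UNITS[ind]
                w.writerow([f"band:{ind}", f"tier{b.tier_index}", "lower_bound",
                            "" if b.lower_bound is None else b.lower_bound, u])
                w.writerow([f"band:{ind}", f"tier{b.tier_index}", "upper_bound",
                            "" if b.upper_bound is None else b.upper_bound, u])
                w.writerow([f"band:{ind}", f"tier{b.tier_index}",
                            "representative_value", b.representative_value, u])
        for label, t in self.targets.items():
            unit = "ug/m3" if t.pollutant == PM25 else "mg/m3"
            w.writerow(["target", label, t.pollutant, t.level, unit])
        return buf.getvalue()


def builtin_registry() -> Registry:
    """The default registry: IWA tier representative values, the three-stone
    fire (tier 0 on every indicator), a traditional charcoal stove, and the
    WHO PM2.5 interim-1 / final and CO 24-hr targets.

    Tier 1-4 representative emission rates are the midpoints of the printed
    tier boundaries (zero as the lower boundary of the emissions tier 4);
    tier 4 thermal efficiency is 50%, extrapolated from tiers 1-3.
    """
    stoves = {
        "tsf": StovePerformance("tsf", pm_rate=40.0, co_rate=970.0,
                                thermal_efficiency=0.15),
        "tier1": StovePerformance("tier1", pm_rate=28.5, co_rate=795.0,
                                  thermal_efficiency=0.20),
        "tier2": StovePerformance("tier2", pm_rate=12.5, co_rate=555.0,
                                  thermal_efficiency=0.30),
        "tier3": StovePerformance("tier3", pm_rate=5.0, co_rate=455.0,
                                  thermal_efficiency=0.40),
        "tier4": StovePerformance("tier4", pm_rate=1.0, co_rate=210.0,
                                  thermal_efficiency=0.50),
        "charcoal_traditional": StovePerformance(
            "charcoal_traditional", pm_rate=15.0, co_rate=1300.0,
            thermal_efficiency=0.25),
    }
    bands = {
        PM_INDOOR: (
            TierBand(PM_INDOOR, 0, 40.0, None, 40.0),
            TierBand(PM_INDOOR, 1, 17.0, 40.0, 28.5),
            TierBand(PM_INDOOR, 2, 8.0, 17.0, 12.5),
            TierBand(PM_INDOOR, 3, 2.0, 8.0, 5.0),
            TierBand(PM_INDOOR, 4, 0.0, 2.0, 1.0),
        ),
        CO_INDOOR: (
            TierBand(CO_INDOOR, 0, 970.0, None, 970.0),
            TierBand(CO_INDOOR, 1, 620.0, 970.0, 795.0),
            TierBand(CO_INDOOR, 2, 490.0, 690.0, 555.0),
            TierBand(CO_INDOOR, 3, 420.0, 490.0, 455.0),
            TierBand(CO_INDOOR, 4, 0.0, 420.0, 210.0),
        ),
        THERMAL_EFFICIENCY: (
            TierBand(THERMAL_EFFICIENCY, 0, 0.0, 0.15, 0.15),
            TierBand(THERMAL_EFFICIENCY, 1, 0.15, 0.25, 0.20),
            TierBand(THERMAL_EFFICIENCY, 2, 0.25, 0.35, 0.30),
            TierBand(THERMAL_EFFICIENCY, 3, 0.35, 0.45, 0.40),
            TierBand(THERMAL_EFFICIENCY, 4, 0.45, 1.0, 0.50),
        ),
    }
    targets = {
        "pm25_interim1": GuidelineTarget(PM25, 35.0, "pm25_interim1"),
        "pm25_final": GuidelineTarget(PM25, 10.0, "pm25_final"),
        "co_24hr": GuidelineTarget(CO, 7.0, "co_24hr"),
    }
    return Registry(stoves=stoves, bands=bands, targets=targets)


def classify_tier(
    value: float,
    indicator: str,
    bands: tuple[TierBand, ...] | None = None,
) -> int:
    """Tier index for ``value`` on ``indicator``.

    A value contained in more than one band (shared endpoints, or the printed
    CO overlap at 620-690 mg/min) is assigned the cleaner band, i.e. the
    higher tier index.  A value outside every band — possible only with
    malformed custom bands, since the built-in bands tile the half-line — is
    mapped to the nearest band with a :class:`GapValueWarning`.
    """
    if bands is None:
        bands = builtin_registry().bands[indicator]
    if indicator == THERMAL_EFFICIENCY:
        if not 0 < value <= 1:
            raise ValueError(f"efficiency must be in (0, 1], got {value}")
    elif value < 0:
        raise ValueError(f"emission rate must be >= 0, got {value}")

    hits = [b.tier_index for b in bands if b.contains(value)]
    if hits:
        return max(hits)
    nearest = min(bands, key=lambda b: b.distance(value))
    warnings.warn(
        f"{value} falls outside every {indicator} band; "
        f"assigning nearest tier {nearest.tier_index}",
        GapValueWarning,
        stacklevel=2,
    )
    return nearest.tier_index
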