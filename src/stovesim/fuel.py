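"""Fuel savings from thermal-efficiency ratios.

A new stove of thermal efficiency ``eta_new`` displacing fraction ``d`` of
the cooking done on a traditional stove of efficiency ``eta_traditional``
saves the fraction

    savings = (1 - eta_traditional / eta_new) * d

of the traditional fuel demand, assuming the same useful cooking energy is
delivered.  Savings are dimensionless fractions internally; multiply by 100
for percent at reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .registry import THERMAL_EFFICIENCY, TierBand

__all__ = [
    "FuelScenario",
    "UnreachableSavingsError",
    "fuel_savings",
    "displacement_for_savings",
    "savings_band",
]


class UnreachableSavingsError(ValueError):
    """The savings target exceeds what full displacement can deliver."""


@dataclass(frozen=True)
class FuelScenario:
    """Traditional and new stove efficiencies plus a displacement fraction.

    By default the new stove must be at least as efficient as the
    traditional one (the savings formula presupposes an improvement); pass
    ``allow_negative=True`` to evaluate regressions.
    """

    eta_traditional: float
    eta_new: float
    displacement: float
    allow_negative: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.eta_traditional <= 1:
            raise ValueError(f"eta_traditional must be in (0, 1], got {self.eta_traditional}")
        if not 0 < self.eta_new <= 1:
            raise ValueError(f"eta_new must be in (0, 1], got {self.eta_new}")
        if not 0 <= self.displacement <= 1:
            raise ValueError(f"displacement must be in [0, 1], got {self.displacement}")
        if self.eta_new < self.eta_traditional and not self.allow_negative:
            raise ValueError(
                f"eta_new {self.eta_new} < eta_traditional {self.eta_traditional} "
                "implies negative savings; pass allow_negative=True to evaluate"
            )


def fuel_savings(fs: FuelScenario) -> float:
    """Fraction of fuel saved: ``(1 - eta_traditional/eta_new) * d``, exact."""
    return (1.0 - fs.eta_traditional / fs.eta_new) * fs.displacement


def displacement_for_savings(
    eta_traditional: float, eta_new: float, target: float
) -> float:
    """Displacement fraction needed for a fuel-savings target.

    Exact inversion ``d = target / (1 - eta_traditional/eta_new)``; raises
    :class:`UnreachableSavingsError` when the target exceeds the full-
    displacement savings.
    """
    if not 0 <= target < 1:
        raise ValueError(f"target must be in [0, 1), got {target}")
    if target == 0:
        return 0.0
    slope = 1.0 - eta_traditional / eta_new
    if slope <= 0:
        raise UnreachableSavingsError(
            f"new stove (eta {eta_new}) saves no fuel over baseline (eta {eta_traditional})"
        )
    d = target / slope
    if d > 1 + 1e-12:
        raise UnreachableSavingsError(
            f"target {target:.0%} unreachable: full displacement saves only {slope:.1%}"
        )
    return min(float(d), 1.0)


def savings_band(
    band: TierBand,
    baseline_eta: float,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Within-tier fuel-savings envelope across displacement.

    Evaluates the savings curve with the new-stove efficiency at the tier
    band's lower bound, representative value and upper bound; savings being
    monotone in efficiency, the representative curve is bracketed by the
    bound curves.  Bound efficiencies below the baseline yield negative
    savings and are reported as such (the envelope is informational).
    """
    if band.indicator != THERMAL_EFFICIENCY:
        raise ValueError(f"expected a thermal-efficiency band, got {band.indicator}")
    if grid is None:
        grid = np.linspace(0.0, 1.0, 21)
    rows = []
    bounds = {
        "lower": band.lower_bound,
        "representative": band.representative_value,
        "upper": band.upper_bound,
    }
    for bound_name, eta in bounds.items():
        if eta is None or eta <= 0:
            continue
        for d in np.asarray(grid, dtype=float):
            fs = FuelScenario(baseline_eta, float(eta), float(d), allow_negative=True)
            rows.append(
                {
                    "tier": band.tier_index,
                    "bound": bound_name,
                    "eta_new": float(eta),
                    "eta_traditional": baseline_eta,
                    "displacement": float(d),
                    "fuel_savings_fraction": fuel_savings(fs),
                }
            )
    return pd.DataFrame(rows)
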