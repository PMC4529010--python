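"""Reporting-precision helpers.

Model outputs carry full precision internally.  For presentation alongside
published guidance figures, usage times are conventionally rounded to the
nearest 5 minutes (or down to 5 minutes where a conservative bound is
wanted), displacement fractions and source shares to the nearest percent,
and concentrations to the nearest 1 ug/m3.
"""

from __future__ import annotations

import math

__all__ = [
    "round_to_nearest",
    "floor_to_nearest",
    "usage_minutes",
    "percent",
    "concentration_ug",
]


def round_to_nearest(x: float, step: float) -> float:
    """Round ``x`` to the nearest multiple of ``step`` (half away from zero)."""
    if step <= 0:
        raise ValueError("step must be positive")
    q = x / step
    return step * math.floor(q + 0.5) if q >= 0 else -step * math.floor(-q + 0.5)


def floor_to_nearest(x: float, step: float) -> float:
    """Round ``x`` down to a multiple of ``step`` (conservative bound)."""
    if step <= 0:
        raise ValueError("step must be positive")
    return step * math.floor(x / step)


def usage_minutes(minutes: float, mode: str = "nearest") -> float:
    """Usage time to a 5-minute grid; ``mode='floor'`` gives the conservative
    (never-exceeding) bound."""
    if mode == "nearest":
        return round_to_nearest(minutes, 5.0)
    if mode == "floor":
        return floor_to_nearest(minutes, 5.0)
    raise ValueError(f"unknown rounding mode {mode!r}")


def percent(fraction: float) -> float:
    """A fraction as a whole percent."""
    return round_to_nearest(100.0 * fraction, 1.0)


def concentration_ug(value_ug: float) -> float:
    """Concentration to the nearest 1 ug/m3."""
    return round_to_nearest(value_ug, 1.0)
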