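"""Single-zone well-mixed kitchen concentration model.

A kitchen of volume ``V`` (m3) ventilated at a nominal air-exchange rate of
``ach`` changes per hour loses pollutant at the first-order rate
``alpha = ach / 60`` per minute.  With a constant indoor emission rate ``G``
(mg/min) the concentration obeys the exact solution

    C(t) = G / (alpha V) * (1 - exp(-alpha t)) + C0 * exp(-alpha t),

which the simulator applies minute by minute over a piecewise-constant
emission schedule; there is no time-discretisation (Euler) error, only the
choice of the 1-minute reporting grid.  Per-source traces are obtained by
superposition: each source is a linear input to the same filter.

All concentrations are carried internally in mg/m3 for both PM2.5 and CO;
PM2.5 is converted to ug/m3 only at reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .registry import PM25

__all__ = [
    "Kitchen",
    "Segment",
    "EmissionSchedule",
    "ConcentrationSeries",
    "step_concentration",
    "simulate_day",
    "daily_mean",
    "closed_form_daily_mean",
    "DEFAULT_EVENT_STARTS",
]

# Default cooking day: three 1-hr events at 07:00, 12:00 and 18:00.  Only
# "three 1-hr events" is prescribed by the modelling convention; the start
# times are a configuration knob, and daily means are placement-insensitive
# at the default ventilation (tested).
DEFAULT_EVENT_STARTS = (420, 720, 1080)


@dataclass(frozen=True)
class Kitchen:
    """Room volume (m3) and nominal air-exchange rate (changes per hour)."""

    volume: float
    ach: float

    def __post_init__(self) -> None:
        if not self.volume > 0:
            raise ValueError(f"volume must be > 0, got {self.volume}")
        if not self.ach > 0:
            raise ValueError(f"ach must be > 0, got {self.ach}")

    @property
    def alpha(self) -> float:
        """First-order loss rate, per minute."""
        return self.ach / 60.0


@dataclass(frozen=True)
class Segment:
    """A constant-rate emission interval: ``rate`` mg/min over
    [start, start + duration) minutes, attributed to ``source``."""

    start: float
    duration: float
    rate: float
    source: str = "stove"

    def __post_init__(self) -> None:
        if self.start < 0 or self.duration <= 0:
            raise ValueError("segment must have start >= 0 and duration > 0")
        if self.rate < 0 or not math.isfinite(self.rate):
            raise ValueError(f"emission rate must be finite and >= 0, got {self.rate}")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass
class EmissionSchedule:
    """Timed, source-attributed emission segments over a 24-hr horizon.

    Segments of the *same* source must not overlap (a stove cannot run twice
    at once); segments of different sources may coincide, which is how a
    displacement scenario co-locates the baseline and new stove within the
    same cooking events.
    """

    segments: list[Segment] = field(default_factory=list)
    horizon_minutes: int = 1440

    def __post_init__(self) -> None:
        if self.horizon_minutes <= 0:
            raise ValueError("horizon must be positive")
        for s in self.segments:
            if s.end > self.horizon_minutes + 1e-9:
                raise ValueError(
                    f"segment [{s.start}, {s.end}) exceeds horizon "
                    f"{self.horizon_minutes}"
                )
        by_source: dict[str, list[Segment]] = {}
        for s in self.segments:
            by_source.setdefault(s.source, []).append(s)
        for source, segs in by_source.items():
            segs = sorted(segs, key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start < a.end - 1e-9:
                    raise ValueError(
                        f"overlapping segments for source {source!r}: "
                        f"[{a.start},{a.end}) and [{b.start},{b.end})"
                    )

    @property
    def sources(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.segments:
            seen.setdefault(s.source)
        return list(seen)

    def minutes_on(self, source: str | None = None) -> float:
        return sum(
            s.duration for s in self.segments if source is None or s.source == source
        )

    def rate_array(self, source: str | None = None) -> np.ndarray:
        """Per-minute emission rate (mg/min) for one source or all sources.

        Fractional segment boundaries are spread pro-rata over the straddled
        minute, preserving emitted mass exactly.
        """
        g = np.zeros(self.horizon_minutes)
        for s in self.segments:
            if source is not None and s.source != source:
                continue
            lo, hi = s.start, s.end
            i0, i1 = int(math.floor(lo)), int(math.ceil(hi))
            for i in range(i0, min(i1, self.horizon_minutes)):
                overlap = min(hi, i + 1) - max(lo, i)
                if overlap > 0:
                    g[i] += s.rate * overlap
        return g

    @classmethod
    def cooking_events(
        cls,
        rate: float,
        starts: tuple[float, ...] = DEFAULT_EVENT_STARTS,
        duration: float = 60.0,
        source: str = "stove",
        horizon_minutes: int = 1440,
    ) -> "EmissionSchedule":
        """Schedule of equal-length cooking events at a constant rate."""
        return cls(
            segments=[Segment(t, duration, rate, source) for t in starts],
            horizon_minutes=horizon_minutes,
        )


@dataclass
class ConcentrationSeries:
    """Minute-indexed concentration trace with per-source components.

    ``values[t]`` is the concentration (mg/m3) at the end of minute ``t``.
    ``integral`` is the exact time integral of the underlying continuous
    solution over the horizon (mg.min/m3), computed analytically per minute,
    so the mass balance  alpha*V*integral + V*(C_end - C_start) = emitted
    mass  holds to machine precision.
    """

    pollutant: str
    kitchen: Kitchen
    values: np.ndarray
    components: dict[str, np.ndarray]
    integral: float
    c_initial: float = 0.0

    def daily_mean(self) -> float:
        """Exact time-averaged concentration over the horizon, mg/m3."""
        return self.integral / len(self.values)

    def daily_mean_ug(self) -> float:
        """Daily mean in the reporting unit: ug/m3 for PM2.5, mg/m3 for CO."""
        m = self.daily_mean()
        return m * 1000.0 if self.pollutant == PM25 else m

    def component_means(self) -> dict[str, float]:
        """Time-averaged per-source contributions (sample average), mg/m3."""
        return {k: float(v.mean()) for k, v in self.components.items()}

    def to_frame(self) -> pd.DataFrame:
        """Tidy (minute, pollutant, source, concentration) table in mg/m3."""
        rows = [
            pd.DataFrame(
                {
                    "minute": np.arange(1, len(self.values) + 1),
                    "pollutant": self.pollutant,
                    "source": "total",
                    "concentration_mg_m3": self.values,
                }
            )
        ]
        for src, v in self.components.items():
            rows.append(
                pd.DataFrame(
                    {
                        "minute": np.arange(1, len(v) + 1),
                        "pollutant": self.pollutant,
                        "source": src,
                        "concentration_mg_m3": v,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def step_concentration(c_prev: float, g: float, kitchen: Kitchen, dt: float) -> float:
    """One exact update of the box model over ``dt`` minutes at constant
    emission ``g`` (mg/min): ``(g/(alpha V))(1-e^(-alpha dt)) + c_prev e^(-alpha dt)``.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if c_prev < 0 or g < 0:
        raise ValueError("c_prev and g must be nonnegative")
    if not (math.isfinite(c_prev) and math.isfinite(g)):
        raise ValueError("inputs must be finite")
    decay = math.exp(-kitchen.alpha * dt)
    return g / (kitchen.alpha * kitchen.volume) * (1.0 - decay) + c_prev * decay


def _filter_minutes(g: np.ndarray, kitchen: Kitchen, c0: float) -> np.ndarray:
    """End-of-minute concentrations for a per-minute rate array.

    The recursion c[t] = (1-k)/(alpha V) * g[t] + k * c[t-1] with
    k = exp(-alpha) is a first-order IIR filter; scipy.signal.lfilter runs
    it in C.
    """
    k = math.exp(-kitchen.alpha)
    b = [(1.0 - k) / (kitchen.alpha * kitchen.volume)]
    a = [1.0, -k]
    out, _ = lfilter(b, a, g, zi=np.array([k * c0]))
    return out


def _exact_integral(g: np.ndarray, c: np.ndarray, kitchen: Kitchen, c0: float) -> float:
    """Exact integral of the continuous solution over the horizon.

    Within a minute at constant rate g the integral is
    ss + (c_start - ss) * (1 - k) / alpha  with ss = g/(alpha V).
    """
    alpha = kitchen.alpha
    k = math.exp(-alpha)
    ss = g / (alpha * kitchen.volume)
    c_start = np.concatenate(([c0], c[:-1]))
    return float(np.sum(ss + (c_start - ss) * (1.0 - k) / alpha))


def simulate_day(
    schedule: EmissionSchedule,
    kitchen: Kitchen,
    c_initial: float = 0.0,
    pollutant: str = PM25,
    background: float = 0.0,
) -> ConcentrationSeries:
    """Minute-resolution simulation of a full schedule.

    Per-source component traces are computed by simulating each source alone
    (superposition); a nonzero initial concentration decays as its own
    ``"carryover"`` component and a constant ``background`` (mg/m3), default
    off, is added as an ``"ambient"`` component.  The component traces sum
    to the total trace exactly up to floating-point roundoff.
    """
    if c_initial < 0 or background < 0:
        raise ValueError("c_initial and background must be nonnegative")
    n = schedule.horizon_minutes
    total = _filter_minutes(schedule.rate_array(), kitchen, c_initial)
    components: dict[str, np.ndarray] = {}
    for src in schedule.sources:
        components[src] = _filter_minutes(schedule.rate_array(src), kitchen, 0.0)
    if c_initial > 0:
        t = np.arange(1, n + 1)
        components["carryover"] = c_initial * np.exp(-kitchen.alpha * t)
    integral = _exact_integral(schedule.rate_array(), total, kitchen, c_initial)
    if background > 0:
        total = total + background
        components["ambient"] = np.full(n, background)
        integral += background * n
    return ConcentrationSeries(
        pollutant=pollutant,
        kitchen=kitchen,
        values=total,
        components=components,
        integral=integral,
        c_initial=c_initial,
    )


def daily_mean(series: ConcentrationSeries) -> float:
    """24-hr mean concentration of a series, mg/m3."""
    if len(series.values) == 0:
        raise ValueError("empty series")
    return series.daily_mean()


def closed_form_daily_mean(
    g_effective: float,
    minutes_on: float,
    kitchen: Kitchen,
    horizon_minutes: int = 1440,
) -> float:
    """Mass-balance shortcut for the daily mean, mg/m3.

    All emitted mass ``G * t_on`` is removed by ventilation within the
    horizon when the decay tail is negligible, so the time-averaged
    concentration is ``G * t_on / (alpha * V * horizon)``.  Exact only when
    emissions end early enough for the tail to decay (at 15 ACH, ~1 hr
    suffices for < 0.01% error).
    """
    if not 0 <= minutes_on <= horizon_minutes:
        raise ValueError(f"minutes_on must be in [0, {horizon_minutes}]")
    if g_effective < 0:
        raise ValueError("g_effective must be nonnegative")
    return g_effective * minutes_on / (kitchen.alpha * kitchen.volume * horizon_minutes)
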