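"""Run configuration and regeneration of the headline guidance tables.

:func:`report_guidance_matrix` produces the performance-usage target matrix:
for each kitchen-concentration target and candidate new-stove tier, the
minimum displacement of the three-stone fire and the equivalent weekly hours
on each stove (3 hr/day x 7 = a 21-hour cooking week).
:func:`reproduce_all` writes the full set of tidy CSV tables behind the
package's standard outputs (usage limits, displacement sweeps, source
shares, exposure/relative-risk curves, fuel savings, within-tier envelopes)
plus a JSON run log, atomically.
"""

from __future__ import annotations

import json
import shutil
import tempfile
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .boxmodel import Kitchen
from .exposure import demo_alri_parameters, rr_curve
from .fixtures import FixtureRanges
from .fuel import savings_band
from .registry import (
    CO,
    PM25,
    PM_INDOOR,
    CO_INDOOR,
    THERMAL_EFFICIENCY,
    Registry,
    builtin_registry,
)
from .rounding import percent, usage_minutes
from .scenarios import (
    UnreachableTargetError,
    displacement_sweep,
    required_displacement,
    tier_band_sweep,
    tier_usage_limits,
)

__all__ = ["RunConfig", "report_guidance_matrix", "reproduce_all"]

WEEKLY_COOKING_HOURS = 21.0  # 3 hr/day x 7 days


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected."""

    volume_m3: float = 30.0
    ach: float = 15.0
    total_cooking_minutes: float = 180.0
    matrix_pm_levels_ug: tuple[float, ...] = (333.0, 166.0, 35.0)
    matrix_tiers: tuple[str, ...] = ("tier1", "tier2", "tier3", "tier4")
    sweep_grid_step: float = 0.05
    seed: int = 0
    rounding: str = "full_precision"  # or "paper_rounding"

    def __post_init__(self) -> None:
        if self.rounding not in ("full_precision", "paper_rounding"):
            raise ValueError(f"unknown rounding mode {self.rounding!r}")
        if not 0 < self.sweep_grid_step <= 1:
            raise ValueError("sweep_grid_step must be in (0, 1]")
        # validate kitchen/cooking values via the domain types
        Kitchen(volume=self.volume_m3, ach=self.ach)
        if not 0 < self.total_cooking_minutes <= 1440:
            raise ValueError("total_cooking_minutes must be in (0, 1440]")

    @property
    def kitchen(self) -> Kitchen:
        return Kitchen(volume=self.volume_m3, ach=self.ach)

    @property
    def grid(self) -> np.ndarray:
        n = int(round(1.0 / self.sweep_grid_step))
        return np.linspace(0.0, 1.0, n + 1)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("matrix_pm_levels_ug", "matrix_tiers"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def report_guidance_matrix(
    config: RunConfig | None = None, registry: Registry | None = None
) -> pd.DataFrame:
    """Performance-usage target matrix.

    One row per (kitchen PM2.5 target level, new-stove tier): the minimum
    three-stone-fire displacement reaching the target, and the weekly hours
    spent on each stove out of the 21-hour cooking week; unreachable
    combinations are flagged rather than omitted.
    """
    config = config or RunConfig()
    registry = registry or builtin_registry()
    tsf = registry["tsf"]
    rows = []
    for level in config.matrix_pm_levels_ug:
        for tier_name in config.matrix_tiers:
            stove = registry[tier_name]
            try:
                d = required_displacement(
                    tsf,
                    stove,
                    config.kitchen,
                    pollutant=PM25,
                    target_level=level,
                    basis="kitchen",
                    total_cooking_minutes=config.total_cooking_minutes,
                )
                reachable = True
            except UnreachableTargetError:
                d, reachable = float("nan"), False
            d_report = percent(d) / 100.0 if (
                reachable and config.rounding == "paper_rounding"
            ) else d
            rows.append(
                {
                    "target_pm25_ug_m3": level,
                    "new_stove": tier_name,
                    "reachable": reachable,
                    "required_displacement": d_report,
                    "tsf_hours_per_week": (1.0 - d) * WEEKLY_COOKING_HOURS
                    if reachable else float("nan"),
                    "new_stove_hours_per_week": d * WEEKLY_COOKING_HOURS
                    if reachable else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def reproduce_all(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Regenerate every standard output table under ``outdir``.

    Writes eight tidy CSV tables plus ``run_log.json``.  The write is
    atomic: tables are assembled in a temporary directory and moved into
    place only if every one succeeds, so a failed run leaves no partial
    output.  Given the same config the byte content is reproducible.
    """
    outdir = Path(outdir)
    registry = builtin_registry()
    kitchen = config.kitchen
    tsf = registry["tsf"]
    charcoal = registry["charcoal_traditional"]
    tiers = [registry[t] for t in ("tier1", "tier2", "tier3", "tier4")]
    mode = "floor" if config.rounding == "paper_rounding" else None

    usage = tier_usage_limits(registry.stoves, kitchen, registry.targets)
    if mode:
        usage["max_usage_min_per_day"] = [
            usage_minutes(v, "floor") for v in usage["max_usage_min_per_day"]
        ]

    tables: dict[str, pd.DataFrame] = {
        "usage_limits": usage,
        "tsf_displacement_sweep": displacement_sweep(
            tsf, tiers, kitchen, config.grid,
            total_cooking_minutes=config.total_cooking_minutes),
        "charcoal_displacement_sweep": displacement_sweep(
            charcoal, tiers, kitchen, config.grid,
            total_cooking_minutes=config.total_cooking_minutes),
        "tier_band_envelopes_pm25": tier_band_sweep(
            registry.bands[PM_INDOOR], tsf, kitchen, config.grid,
            total_cooking_minutes=config.total_cooking_minutes),
        "tier_band_envelopes_co": tier_band_sweep(
            registry.bands[CO_INDOOR], tsf, kitchen, config.grid,
            total_cooking_minutes=config.total_cooking_minutes),
        "relative_risk_curve": rr_curve(
            demo_alri_parameters(), np.linspace(0.0, 450.0, 451)),
        "fuel_savings_bands": pd.concat(
            [
                savings_band(band, tsf.thermal_efficiency, config.grid)
                for band in registry.bands[THERMAL_EFFICIENCY]
                if band.tier_index > 0
            ],
            ignore_index=True,
        ),
        "guidance_matrix": report_guidance_matrix(config, registry),
    }

    tmp = Path(tempfile.mkdtemp(prefix="stovesim_"))
    try:
        paths: dict[str, Path] = {}
        for name, df in tables.items():
            p = tmp / f"{name}.csv"
            df.to_csv(p, index=False, float_format="%.10g")
            paths[name] = outdir / f"{name}.csv"
        log = {
            "package": "stovesim",
            "version": __version__,
            "seed": config.seed,
            "config": {
                "volume_m3": config.volume_m3,
                "ach": config.ach,
                "total_cooking_minutes": config.total_cooking_minutes,
                "rounding": config.rounding,
                "sweep_grid_step": config.sweep_grid_step,
            },
            "tables": sorted(tables),
        }
        (tmp / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
        paths["run_log"] = outdir / "run_log.json"
        outdir.mkdir(parents=True, exist_ok=True)
        for f in tmp.iterdir():
            shutil.move(str(f), outdir / f.name)
        return paths
    finally:
        shutil.rmtree(tmp, ignore_errors=True)
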