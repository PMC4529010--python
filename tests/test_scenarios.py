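"""Scenario engine: blending, apportionment, and both model inversions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stovesim import (
    DisplacementScenario,
    GuidelineTarget,
    UnreachableTargetError,
    blended_rate,
    evaluate_scenario,
    max_usage_minutes,
    required_displacement,
    displacement_sweep,
    tier_band_sweep,
    tier_usage_limits,
)
from stovesim.registry import CO, PM25
from stovesim.rounding import percent, usage_minutes


class TestBlendedRate:
    def test_half_displacement(self):
        assert blended_rate(40.0, 1.0, 0.5) == pytest.approx(20.5)

    def test_identical_stoves(self):
        assert blended_rate(7.0, 7.0, 0.3) == 7.0

    def test_full_displacement(self):
        assert blended_rate(40.0, 1.0, 1.0) == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            blended_rate(40.0, 1.0, 1.2)


class TestEvaluateScenario:
    def test_exclusive_tsf_baseline(self, registry, kitchen):
        res = evaluate_scenario(
            DisplacementScenario(registry["tsf"], registry["tier4"], 0.0), kitchen
        )
        assert res.mean_reporting_units(PM25) == pytest.approx(667, rel=5e-3)
        assert res.shares[PM25]["baseline"] == pytest.approx(1.0)
        assert not res.meets.get("pm25_interim1", False)

    @pytest.mark.parametrize(
        "new, pollutant, share",
        [
            ("tier4", PM25, 0.98),  # 40 / 41
            ("tier3", PM25, 0.89),  # 40 / 45
            ("tier4", CO, 0.82),    # 970 / 1180
            ("tier3", CO, 0.68),    # 970 / 1425
        ],
    )
    def test_tsf_source_shares_at_half_displacement(
        self, registry, kitchen, new, pollutant, share
    ):
        res = evaluate_scenario(
            DisplacementScenario(registry["tsf"], registry[new], 0.5), kitchen
        )
        assert percent(res.shares[pollutant]["baseline"]) == pytest.approx(share * 100)

    def test_share_identity_closed_form(self, registry, kitchen):
        """TSF share equals (1-d) G_base / [(1-d) G_base + d G_new]."""
        d = 0.37
        res = evaluate_scenario(
            DisplacementScenario(registry["tsf"], registry["tier2"], d), kitchen
        )
        for pollutant in (PM25, CO):
            gb = registry["tsf"].emission_rate(pollutant)
            gn = registry["tier2"].emission_rate(pollutant)
            expect = (1 - d) * gb / ((1 - d) * gb + d * gn)
            assert res.shares[pollutant]["baseline"] == pytest.approx(expect, rel=1e-9)

    def test_shares_sum_to_one(self, registry, kitchen):
        res = evaluate_scenario(
            DisplacementScenario(registry["tsf"], registry["tier1"], 0.4), kitchen
        )
        for pollutant in (PM25, CO):
            assert sum(res.shares[pollutant].values()) == pytest.approx(1.0)

    def test_guideline_flags(self, registry, kitchen):
        res = evaluate_scenario(
            DisplacementScenario(registry["tsf"], registry["tier4"], 1.0),
            kitchen,
            targets=registry.targets,
        )
        # exclusive tier-4 use: 16.7 ug/m3 PM and 0.35 mg/m3 CO
        assert res.meets["pm25_interim1"] and res.meets["co_24hr"]
        assert not res.meets["pm25_final"]


class TestMaxUsageMinutes:
    @pytest.mark.parametrize(
        "stove, target, minutes",
        [
            ("tsf", "pm25_interim1", 9.45),       # paper rounds to 10
            ("charcoal_traditional", "pm25_interim1", 25.2),
            ("tsf", "co_24hr", 77.94),            # paper rounds down to 75
            ("charcoal_traditional", "co_24hr", 58.15),
            ("tier4", "co_24hr", 360.0),
        ],
    )
    def test_against_closed_form_oracle(self, registry, kitchen, stove, target, minutes):
        got = max_usage_minutes(registry[stove], kitchen, registry.targets[target])
        assert got == pytest.approx(minutes, abs=0.05)

    def test_paper_rounding_modes(self, registry, kitchen):
        t = max_usage_minutes(registry["tsf"], kitchen, registry.targets["pm25_interim1"])
        assert usage_minutes(t, "nearest") == 10
        t_co = max_usage_minutes(registry["tsf"], kitchen, registry.targets["co_24hr"])
        assert usage_minutes(t_co, "floor") == 75

    def test_returned_value_meets_target_and_epsilon_more_does_not(
        self, registry, kitchen
    ):
        from stovesim.scenarios import _mean_single_stove

        tgt = registry.targets["pm25_interim1"]
        t = max_usage_minutes(registry["tsf"], kitchen, tgt)
        g = registry["tsf"].pm_rate
        # brentq xtol is 0.01 min, worth ~0.1% of the level for the TSF
        assert _mean_single_stove(g, t, kitchen) <= tgt.level_mg_m3 * (1 + 2e-3)
        assert _mean_single_stove(g, t + 0.5, kitchen) > tgt.level_mg_m3

    def test_zero_rate_rejected(self, kitchen, registry):
        from stovesim import StovePerformance

        smokeless = StovePerformance("x", 0.0, 10.0, 0.5)
        with pytest.raises(ValueError):
            max_usage_minutes(smokeless, kitchen, registry.targets["pm25_interim1"])


class TestRequiredDisplacement:
    def test_kitchen_concentration_goal_166(self, registry, kitchen):
        d = required_displacement(
            registry["tsf"], registry["tier4"], kitchen, target_level=166.0
        )
        assert percent(d) == 77

    def test_exposure_goal_who_interim1(self, registry, kitchen):
        d = required_displacement(
            registry["tsf"], registry["tier4"], kitchen,
            target_level=35.0, basis="exposure",
        )
        assert percent(d) == 94

    @pytest.mark.parametrize(
        "new, reduction, expect_pct",
        [
            ("tier2", 0.50, 73), ("tier3", 0.50, 57), ("tier4", 0.50, 51),
            ("tier3", 0.75, 86), ("tier4", 0.75, 77),
        ],
    )
    def test_fractional_reduction_goals(self, registry, kitchen, new, reduction, expect_pct):
        d = required_displacement(
            registry["tsf"], registry[new], kitchen, target_reduction=reduction
        )
        assert percent(d) == expect_pct

    def test_zero_reduction_needs_zero_displacement(self, registry, kitchen):
        assert required_displacement(
            registry["tsf"], registry["tier4"], kitchen, target_reduction=0.0
        ) == 0.0

    def test_unreachable_goal_signals(self, registry, kitchen):
        with pytest.raises(UnreachableTargetError):
            required_displacement(
                registry["tsf"], registry["tier1"], kitchen, target_level=35.0
            )

    def test_inversion_consistency(self, registry, kitchen):
        """The goal is met at the returned d and violated at d - 0.005."""
        level = 166.0
        d = required_displacement(
            registry["tsf"], registry["tier3"], kitchen, target_level=level
        )
        for dd, ok in ((d, True), (d - 0.005, False)):
            res = evaluate_scenario(
                DisplacementScenario(registry["tsf"], registry["tier3"], dd), kitchen
            )
            assert (res.mean_reporting_units(PM25) <= level * (1 + 1e-6)) is ok


class TestSweeps:
    def test_endpoints_and_affinity(self, registry, kitchen):
        df = displacement_sweep(
            registry["tsf"], [registry["tier4"]], kitchen, np.array([0.0, 0.5, 1.0])
        )
        pm = df[df.pollutant == PM25].sort_values("displacement")
        vals = pm.mean_reporting.to_numpy()
        assert vals[0] == pytest.approx(667, rel=5e-3)
        assert vals[2] == pytest.approx(16.7, rel=5e-3)
        # affine: midpoint value is the mean of the endpoints
        assert vals[1] == pytest.approx((vals[0] + vals[2]) / 2, rel=1e-9)

    def test_d0_row_identical_across_new_stoves(self, registry, kitchen):
        df = displacement_sweep(
            registry["tsf"],
            [registry["tier1"], registry["tier4"]],
            kitchen,
            np.array([0.0]),
        )
        pm = df[df.pollutant == PM25]
        assert pm.mean_mg_m3.nunique() == 1

    def test_charcoal_baseline_sweep_properties(self, registry, kitchen):
        df = displacement_sweep(
            registry["charcoal_traditional"], [registry["tier4"]], kitchen,
            np.linspace(0, 1, 5),
        )
        co = df[df.pollutant == CO].sort_values("displacement")
        vals = co.mean_mg_m3.to_numpy()
        diffs = np.diff(vals)
        assert np.allclose(diffs, diffs[0], rtol=1e-9)  # affine
        assert vals[0] == pytest.approx(1300 * 180 / 10800, rel=5e-3)

    def test_tier_band_envelope(self, registry, kitchen):
        df = tier_band_sweep(registry.bands["pm_indoor_emissions"], registry["tsf"],
                             kitchen, np.array([0.0, 1.0]))
        t3 = df[(df.tier == 3) & (df.displacement == 1.0)]
        by_bound = t3.set_index("bound").mean_reporting
        assert by_bound["lower"] == pytest.approx(33.3, rel=5e-3)
        assert by_bound["upper"] == pytest.approx(133.3, rel=5e-3)
        assert by_bound["lower"] <= by_bound["representative"] <= by_bound["upper"]
        # tier 0 lower bound reproduces the TSF curve
        t0 = df[(df.tier == 0) & (df.bound == "lower")]
        assert t0[t0.displacement == 1.0].mean_reporting.iloc[0] == pytest.approx(
            667, rel=5e-3
        )

    def test_tier_usage_limits_reports_both_pollutants(self, registry, kitchen):
        df = tier_usage_limits(
            {k: registry[k] for k in ("tier1", "tier2", "tier3", "tier4")},
            kitchen,
            {k: registry.targets[k] for k in ("pm25_interim1", "co_24hr")},
        )
        pm = df[df.target == "pm25_interim1"].set_index("stove").max_usage_min_per_day
        co = df[df.target == "co_24hr"].set_index("stove").max_usage_min_per_day
        # the PM2.5 interim-1 limits are the ~15/30/75/375 min/day ladder
        assert pm["tier1"] == pytest.approx(13.26, abs=0.05)
        assert pm["tier3"] == pytest.approx(75.6, abs=0.1)
        assert pm["tier4"] == pytest.approx(378.0, abs=0.2)
        # the CO-rate limits are a different, larger ladder — both are surfaced
        assert co["tier1"] == pytest.approx(95.1, abs=0.2)
        assert co["tier4"] == pytest.approx(360.0, abs=0.2)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    d=st.floats(0.0, 1.0),
    gb=st.floats(5.0, 45.0),
    gn=st.floats(0.1, 4.9),
)
def test_blended_rate_bracketed_and_monotone(d, gb, gn):
    r = blended_rate(gb, gn, d)
    assert gn <= r <= gb
    assert blended_rate(gb, gn, min(d + 0.1, 1.0)) <= r + 1e-12
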