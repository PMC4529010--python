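"""Box-model correctness: exact step, mass balance, superposition, shortcuts.

The independent oracle for every daily mean here is ventilation mass
balance: all mass emitted within the day is removed at rate alpha*V, so the
time-averaged concentration is (emitted mass - mass still airborne at
midnight) / (alpha * V * horizon).  For schedules ending an hour or more
before midnight the airborne remainder is negligible at 15 ACH.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stovesim import (
    EmissionSchedule,
    Kitchen,
    Segment,
    closed_form_daily_mean,
    daily_mean,
    simulate_day,
    step_concentration,
)

KITCHEN = Kitchen(volume=30.0, ach=15.0)


def mass_balance_mean(schedule: EmissionSchedule, kitchen: Kitchen) -> float:
    """Oracle: emitted mass / (alpha V horizon), ignoring the decayed tail."""
    emitted = sum(s.rate * s.duration for s in schedule.segments)
    return emitted / (kitchen.alpha * kitchen.volume * schedule.horizon_minutes)


class TestStepConcentration:
    def test_no_source_no_carryover(self):
        assert step_concentration(0.0, 0.0, KITCHEN, 5.0) == 0.0

    def test_steady_state_limit(self):
        # G/(alpha V) = 40 / (0.25 * 30)
        assert step_concentration(0.0, 40.0, KITCHEN, 1e7) == pytest.approx(
            40.0 / (0.25 * 30.0), rel=1e-12
        )

    def test_pure_exponential_decay(self):
        c0 = 3.7
        assert step_concentration(c0, 0.0, KITCHEN, 1.0) == pytest.approx(
            c0 * math.exp(-0.25)
        )

    def test_two_half_steps_equal_one_full_step(self):
        # exactness in dt: the update composes without discretisation error
        c_half = step_concentration(1.0, 12.0, KITCHEN, 0.5)
        c_full = step_concentration(c_half, 12.0, KITCHEN, 0.5)
        assert c_full == pytest.approx(step_concentration(1.0, 12.0, KITCHEN, 1.0))

    @pytest.mark.parametrize("bad", [(-1, 0), (0, -1)])
    def test_negative_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            step_concentration(bad[0], bad[1], KITCHEN, 1.0)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            step_concentration(0.0, 1.0, KITCHEN, 0.0)


class TestSimulateDay:
    def test_empty_schedule_is_zero(self):
        ser = simulate_day(EmissionSchedule(), KITCHEN)
        assert np.all(ser.values == 0.0)
        assert daily_mean(ser) == 0.0

    def test_single_block_matches_mass_balance(self):
        sch = EmissionSchedule(segments=[Segment(420, 180, 40.0)])
        ser = simulate_day(sch, KITCHEN)
        assert daily_mean(ser) == pytest.approx(7200.0 / 10800.0, rel=5e-3)

    def test_event_placement_insensitivity(self):
        block = EmissionSchedule(segments=[Segment(420, 180, 40.0)])
        split = EmissionSchedule.cooking_events(40.0, starts=(420, 720, 1080))
        m1 = daily_mean(simulate_day(block, KITCHEN))
        m2 = daily_mean(simulate_day(split, KITCHEN))
        assert m1 == pytest.approx(m2, rel=5e-3)

    def test_superposition_components_sum_to_total(self):
        sch = EmissionSchedule(
            segments=[
                Segment(420, 60, 30.0, "baseline"),
                Segment(420, 60, 2.0, "new"),
                Segment(720, 90, 10.0, "baseline"),
            ]
        )
        ser = simulate_day(sch, KITCHEN)
        total = sum(ser.components.values())
        np.testing.assert_allclose(total, ser.values, rtol=1e-12, atol=1e-15)

    def test_carryover_component_and_decay(self):
        ser = simulate_day(EmissionSchedule(), KITCHEN, c_initial=2.0)
        assert "carryover" in ser.components
        assert ser.values[0] == pytest.approx(2.0 * math.exp(-0.25))
        # at 15 ACH yesterday's air is gone within the hour
        assert ser.values[60] < 2.0 * 1e-6

    def test_background_adds_constant(self):
        ser = simulate_day(EmissionSchedule(), KITCHEN, background=0.01)
        assert daily_mean(ser) == pytest.approx(0.01)

    def test_same_source_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            EmissionSchedule(
                segments=[Segment(0, 60, 1.0, "a"), Segment(30, 60, 1.0, "a")]
            )

    def test_cross_source_overlap_allowed(self):
        sch = EmissionSchedule(
            segments=[Segment(0, 60, 1.0, "a"), Segment(0, 60, 1.0, "b")]
        )
        assert sch.minutes_on() == 120.0

    def test_segment_beyond_horizon_rejected(self):
        with pytest.raises(ValueError, match="horizon"):
            EmissionSchedule(segments=[Segment(1430, 60, 1.0)])


class TestClosedFormDailyMean:
    def test_reference_example(self):
        assert closed_form_daily_mean(40.0, 180.0, KITCHEN) == pytest.approx(
            0.6667, rel=1e-3
        )

    def test_zero_minutes(self):
        assert closed_form_daily_mean(12.0, 0.0, KITCHEN) == 0.0

    @pytest.mark.parametrize("starts", [(0,), (420, 720, 1080), (100, 600)])
    def test_agreement_with_simulation(self, starts):
        n = len(starts)
        sch = EmissionSchedule.cooking_events(25.0, starts=starts, duration=180.0 / n)
        sim = daily_mean(simulate_day(sch, KITCHEN))
        closed = closed_form_daily_mean(25.0, 180.0, KITCHEN)
        assert sim == pytest.approx(closed, rel=5e-3)


# ---------------------------------------------------------------------------
# property tests

kitchens = st.builds(
    Kitchen,
    volume=st.floats(15.0, 60.0),
    ach=st.floats(15.0, 45.0),
)

segment_lists = st.lists(
    st.tuples(
        st.integers(0, 1200),            # start
        st.integers(10, 120),            # duration
        st.floats(0.0, 45.0),            # rate
    ),
    min_size=1,
    max_size=4,
).map(
    lambda raw: [
        Segment(400 * i % 1201, min(dur, 1440 - 400 * i % 1201), rate, f"s{i}")
        for i, (_start, dur, rate) in enumerate(raw)
    ]
)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(kitchen=kitchens, segs=segment_lists)
def test_mass_balance_invariant(kitchen, segs):
    """alpha*V*integral + V*(C_end - C_start) equals emitted mass exactly."""
    sch = EmissionSchedule(segments=segs)
    ser = simulate_day(sch, kitchen)
    emitted = sum(s.rate * s.duration for s in segs)
    recovered = (
        kitchen.alpha * kitchen.volume * ser.integral
        + kitchen.volume * (ser.values[-1] - 0.0)
    )
    assert recovered == pytest.approx(emitted, rel=1e-9, abs=1e-9)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(kitchen=kitchens, rate=st.floats(0.1, 45.0), scale=st.floats(1.1, 4.0))
def test_linearity_in_emission_rate(kitchen, rate, scale):
    base = simulate_day(EmissionSchedule.cooking_events(rate), kitchen)
    scaled = simulate_day(EmissionSchedule.cooking_events(rate * scale), kitchen)
    np.testing.assert_allclose(scaled.values, scale * base.values, rtol=1e-9)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(rate=st.floats(0.5, 45.0), minutes=st.integers(60, 300))
def test_daily_mean_monotone_in_duration(rate, minutes):
    k = KITCHEN
    shorter = EmissionSchedule(segments=[Segment(0, minutes, rate)])
    longer = EmissionSchedule(segments=[Segment(0, minutes + 30, rate)])
    assert daily_mean(simulate_day(longer, k)) > daily_mean(simulate_day(shorter, k))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(kitchen=kitchens, rate=st.floats(0.5, 45.0))
def test_steady_state_reached_within_an_hour(kitchen, rate):
    ser = simulate_day(
        EmissionSchedule(segments=[Segment(0, 120, rate)]), kitchen
    )
    ss = rate / (kitchen.alpha * kitchen.volume)
    assert ser.values[119] == pytest.approx(ss, rel=1e-4)
    assert ser.values[59] == pytest.approx(ss, rel=1e-4)  # within 0.01% at >=15 ACH
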