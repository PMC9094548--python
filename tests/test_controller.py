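"""Control stack: timing arithmetic, PID behaviour, triggering, override,
phase machine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvpsim import (
    ControllerState,
    PIDGains,
    VentSettings,
    breath_timing,
    control_tick,
    detect_breath,
    parse_ie,
    pid_step,
    safety_override,
)
from pvpsim.controller import N_DEBOUNCE, PHASE_EXPIRE, PHASE_INSPIRE
from pvpsim.lung import SensorFrame


def plain_gains(**kw):
    """Gains with the shaping features disabled, for arithmetic checks."""
    defaults = dict(
        kp=0.1, ki=0.0, kd=0.0, deriv_filter_tau=0.0, setpoint_ramp_time=0.0,
        unwind_ratio=1.0,
    )
    defaults.update(kw)
    return PIDGains(**defaults)


class TestSettings:
    def test_requires_exactly_one_timing_spec(self):
        with pytest.raises(ValueError):
            VentSettings(ie_ratio=2.0, t_insp=1.0)
        with pytest.raises(ValueError):
            VentSettings()

    @pytest.mark.parametrize(
        "kw",
        [
            dict(pip_target=70.0, ie_ratio=2.0),
            dict(pip_target=10.0, peep_setting=5.0, ie_ratio=2.0),
            dict(peep_setting=30.0, pip_target=40.0, ie_ratio=2.0),
            dict(respiratory_rate=5.0, ie_ratio=2.0),
            dict(ie_ratio=4.0),
            dict(hapa_limit=80.0, ie_ratio=2.0),
        ],
    )
    def test_label_ranges_enforced(self, kw):
        with pytest.raises(ValueError):
            VentSettings(**kw)

    def test_strict_false_allows_engineering_ranges(self):
        s = VentSettings(respiratory_rate=2.0, t_insp=15.0, strict=False)
        assert breath_timing(s) == (30.0, 15.0, 15.0)

    def test_pip_must_exceed_peep_even_unvalidated(self):
        with pytest.raises(ValueError):
            VentSettings(pip_target=5.0, peep_setting=10.0, ie_ratio=2.0, strict=False)

    def test_default_hapa_limit(self):
        assert VentSettings(pip_target=30, ie_ratio=2.0).hapa_limit == 45.0
        assert VentSettings(pip_target=55, ie_ratio=2.0).hapa_limit == 60.0

    def test_parse_ie(self):
        assert parse_ie("1:2") == 2.0
        assert parse_ie("1:1.5") == 1.5
        with pytest.raises(ValueError):
            parse_ie("2:1")
        with pytest.raises(ValueError):
            parse_ie("1:0")


class TestBreathTiming:
    @pytest.mark.parametrize(
        "kw, expected",
        [
            # pediatric bench settings: RR 25, t_insp 0.6 -> cycle 2.4 s
            (dict(respiratory_rate=25, t_insp=0.6, pip_target=20), (2.4, 0.6, 1.8)),
            (dict(respiratory_rate=10, ie_ratio=1.0), (6.0, 3.0, 3.0)),
            (dict(respiratory_rate=20, ie_ratio=2.0), (3.0, 1.0, 2.0)),
        ],
    )
    def test_timing_arithmetic(self, kw, expected):
        t_cycle, t_insp, t_exp = breath_timing(VentSettings(**kw))
        assert (t_cycle, t_insp, t_exp) == pytest.approx(expected)

    def test_t_insp_exceeding_cycle_rejected(self):
        with pytest.raises(ValueError):
            VentSettings(respiratory_rate=40, t_insp=1.6)


class TestPidStep:
    def test_zero_error_zero_drive(self):
        assert pid_step(30.0, 30.0, plain_gains(), ControllerState(), 0.005) == 0.0

    def test_pure_proportional(self):
        drive = pid_step(30.0, 25.0, plain_gains(), ControllerState(), 0.005)
        assert drive == pytest.approx(0.5)

    def test_flow_adjustment_scales_and_clamps(self):
        drive = pid_step(
            30.0, 25.0, plain_gains(), ControllerState(), 0.005, flow_adjustment=2.0
        )
        assert drive == 1.0  # 2 * 0.1 * 5 clamped

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(e=st.floats(0.01, 4.9), fa=st.floats(0.1, 2.0))
    def test_proportional_linearity(self, e, fa):
        """With ki = kd = 0, doubling the error doubles the unclamped drive
        and flow_adjustment scales it linearly."""
        g = plain_gains()
        d1 = pid_step(30.0, 30.0 - e, g, ControllerState(), 0.005, fa)
        d2 = pid_step(30.0, 30.0 - 2 * e, g, ControllerState(), 0.005, fa)
        if d2 < 1.0:
            assert d2 == pytest.approx(2 * d1, rel=1e-9)
        d3 = pid_step(30.0, 30.0 - e, g, ControllerState(), 0.005, 2 * fa)
        if d3 < 1.0:
            assert d3 == pytest.approx(2 * d1, rel=1e-9)

    def test_drive_always_clamped(self):
        g = plain_gains(kp=10.0)
        assert pid_step(30.0, 0.0, g, ControllerState(), 0.005) == 1.0
        assert pid_step(30.0, 100.0, g, ControllerState(), 0.005) == 0.0

    def test_integral_accumulates_and_is_clamped(self):
        g = PIDGains(kp=0.0, ki=0.5, kd=0.0, integral_clamp=0.2,
                     setpoint_ramp_time=0.0, unwind_ratio=1.0)
        state = ControllerState()
        for _ in range(10000):
            pid_step(30.0, 25.0, g, state, 0.005)
        assert g.ki * state.integral_term == pytest.approx(0.2)

    def test_integral_frozen_when_saturated(self):
        g = PIDGains(kp=1.0, ki=0.5, kd=0.0, setpoint_ramp_time=0.0, unwind_ratio=1.0)
        state = ControllerState()
        pid_step(30.0, 0.0, g, state, 0.005)  # deep saturation
        # only the back-calculation tracking term may move it (downward)
        assert state.integral_term <= 0.0

    def test_unwind_asymmetry(self):
        g = PIDGains(kp=0.0, ki=0.5, kd=0.0, unwind_ratio=4.0, setpoint_ramp_time=0.0)
        s_pos, s_neg = ControllerState(), ControllerState()
        s_pos.integral_term = s_neg.integral_term = 1.0
        pid_step(30.0, 29.0, g, s_pos, 0.005)  # e = +1
        pid_step(30.0, 31.0, g, s_neg, 0.005)  # e = -1
        gained = s_pos.integral_term - 1.0
        lost = 1.0 - s_neg.integral_term
        assert lost == pytest.approx(4.0 * gained, rel=1e-9)


def run_expire_ticks(settings, cstate, pressures, dt=0.005):
    timing = breath_timing(settings)
    hits = []
    for p in pressures:
        hits.append(detect_breath(p, settings, cstate, timing))
    return hits


class TestDetectBreath:
    settings = VentSettings(ie_ratio=2.0, trigger_sensitivity=1.0)

    def expire_state(self, t_in_cycle=3.0):
        s = ControllerState()
        s.phase = PHASE_EXPIRE
        s.time_in_cycle = t_in_cycle
        return s

    def test_flat_pressure_never_triggers(self):
        s = self.expire_state()
        hits = run_expire_ticks(self.settings, s, [5.0] * 50)
        assert not any(hits)

    def test_sustained_dip_triggers_after_debounce(self):
        s = self.expire_state()
        hits = run_expire_ticks(self.settings, s, [2.0] * 10)
        assert hits.index(True) == N_DEBOUNCE - 1

    def test_dip_during_inspiration_ignored(self):
        s = ControllerState()  # INSPIRE
        s.time_in_cycle = 0.5
        hits = run_expire_ticks(self.settings, s, [2.0] * 10)
        assert not any(hits)

    def test_dip_in_refractory_window_ignored(self):
        # refractory covers the first 20% of expiration (t < 1.867 s here)
        s = self.expire_state(t_in_cycle=1.5)
        hits = run_expire_ticks(self.settings, s, [2.0] * 10)
        assert not any(hits)

    def test_interrupted_dip_resets_debounce(self):
        s = self.expire_state()
        hits = run_expire_ticks(self.settings, s, [2.0, 2.0, 5.0, 2.0, 2.0])
        assert not any(hits)


class TestSafetyOverride:
    settings = VentSettings(ie_ratio=2.0, hapa_limit=45.0)

    def test_below_limit_no_override(self):
        s = ControllerState()
        assert not safety_override(30.0, self.settings, s)
        assert not s.override_active

    def test_engages_after_debounce_and_clears(self):
        s = ControllerState()
        raised = [safety_override(50.0, self.settings, s) for _ in range(5)]
        assert raised == [False, False, True, False, False]
        assert s.override_active
        assert not safety_override(40.0, self.settings, s)
        assert not s.override_active


def frame(t, p):
    return SensorFrame(time=t, pressure_reading=p, flow_reading=0.0)


class TestControlTick:
    def test_phase_sequence_and_valve_exclusion(self):
        settings = VentSettings(ie_ratio=2.0, respiratory_rate=15)
        gains = PIDGains()
        s = ControllerState()
        dt = 0.005
        phases = []
        for k in range(1700):  # just over two 4 s cycles
            out = control_tick(frame(k * dt, 15.0), settings, gains, s, dt)
            phases.append(s.phase)
            # a positive drive and an open expiratory valve are exclusive
            assert not (out.valve_drive > 0 and out.expiratory_valve_open)
        arr = np.array(phases)
        switches = np.flatnonzero(np.diff(arr) != 0)
        # strict alternation INSPIRE -> EXPIRE -> INSPIRE ...
        assert all(arr[i] != arr[i + 1] for i in switches)
        assert s.cycle_index == 2

    def test_inspire_then_expire_at_t_insp(self):
        settings = VentSettings(ie_ratio=2.0, respiratory_rate=15)  # t_insp 1.333
        gains = PIDGains()
        s = ControllerState()
        out0 = control_tick(frame(0.0, 5.0), settings, gains, s, 0.005)
        assert s.phase == PHASE_INSPIRE and not out0.expiratory_valve_open
        s.time_in_cycle = 1.34
        out1 = control_tick(frame(1.34, 30.0), settings, gains, s, 0.005)
        assert s.phase == PHASE_EXPIRE
        assert out1.expiratory_valve_open and out1.valve_drive == 0.0

    def test_override_forces_safe_state_until_clear(self):
        settings = VentSettings(ie_ratio=2.0, hapa_limit=45.0)
        gains = PIDGains()
        s = ControllerState()
        t = 0.0
        for _ in range(5):
            out = control_tick(frame(t, 50.0), settings, gains, s, 0.005)
            t += 0.005
        assert s.override_active
        assert out.safety_override and out.valve_drive == 0.0 and out.expiratory_valve_open
        # pressure recovers: override clears, EXPIRE held to cycle boundary
        out = control_tick(frame(t, 30.0), settings, gains, s, 0.005)
        assert not s.override_active
        assert s.phase == PHASE_EXPIRE
        assert not out.safety_override

    def test_cycle_index_monotone_non_decreasing(self):
        settings = VentSettings(ie_ratio=2.0)
        gains = PIDGains()
        s = ControllerState()
        last = 0
        for k in range(4000):
            control_tick(frame(k * 0.005, 15.0), settings, gains, s, 0.005)
            assert s.cycle_index >= last
            last = s.cycle_index
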