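"""Ventilator control stack: breath timing, PID pressure control, spontaneous
breath triggering, and the high-airway-pressure safety override.

The ventilator runs pressure-controlled ventilation as a timed-cycle state
machine with two phases.  During INSPIRE the expiratory solenoid is closed
and a PID loop drives the inspiratory proportional valve to bring airway
pressure to the target PIP (the pressure ramp and plateau are both the PID
transient tracking a constant setpoint).  At the end of the set inspiratory
time the controller switches to EXPIRE: the proportional valve closes and
the expiratory valve opens, letting the lung empty passively down to the
mechanical PEEP valve's setting.  A patient-initiated breath during
expiration shows up as a sharp transient dip below PEEP; when triggering is
armed the controller phase-shifts and starts a new mandatory cycle (SIMV).
A high-pressure safety override sits above everything: sustained pressure
over the alarm limit forces the drive to zero and the expiratory valve open
until pressure falls below the limit, after which normal cycling resumes at
the next cycle boundary.

The `flow_adjustment` setting scales the proportional gain of the PID loop,
which is how the clinician shortens or lengthens the pressure ramp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .lung import SensorFrame

__all__ = [
    "VentSettings",
    "PIDGains",
    "ControllerState",
    "ControlOutput",
    "Phase",
    "parse_ie",
    "breath_timing",
    "pid_step",
    "detect_breath",
    "safety_override",
    "control_tick",
    "BreathController",
]

# Phase codes (also used as the waveform phase channel)
PHASE_INSPIRE = 0
PHASE_EXPIRE = 1


class Phase:
    INSPIRE = PHASE_INSPIRE
    EXPIRE = PHASE_EXPIRE


# Hardware label ranges (Table of specifications): validated by default.
PIP_RANGE = (15.0, 60.0)
PEEP_RANGE = (5.0, 25.0)
RR_RANGE = (10.0, 40.0)
IE_RANGE = (1.0, 3.0)  # the "x" of 1:x
HAPA_MAX = 60.0

# Debounce / refractory defaults: three consecutive control ticks for both
# the breath trigger and the high-pressure override; the trigger is blind
# for the first 20% of expiration to ignore valve-closure transients.
N_DEBOUNCE = 3
TRIGGER_REFRACTORY_FRACTION = 0.2


def parse_ie(text: str) -> float:
    """Parse an I:E ratio of the form '1:x' and return x."""
    parts = str(text).split(":")
    if len(parts) != 2 or parts[0].strip() != "1":
        raise ValueError(f"I:E ratio must have the form '1:x', got {text!r}")
    x = float(parts[1])
    if x <= 0:
        raise ValueError(f"I:E ratio '1:x' needs x > 0, got {text!r}")
    return x


@dataclass(frozen=True)
class VentSettings:
    """Clinician-set ventilation variables.

    Exactly one of ``ie_ratio`` (the x of 1:x) and ``t_insp`` (seconds) must
    be given.  ``hapa_limit`` defaults to min(pip_target + 15, 60) cmH2O.
    ``trigger_sensitivity`` is the pressure drop below set PEEP (cmH2O) that
    flags a patient effort ("breath effort").  ``strict=False`` bypasses the
    hardware label-range validation for engineering/diagnostic runs.
    """

    pip_target: float = 30.0
    peep_setting: float = 5.0
    respiratory_rate: float = 15.0
    ie_ratio: float | None = None
    t_insp: float | None = None
    flow_adjustment: float = 1.0
    trigger_sensitivity: float = 1.0
    hapa_limit: float | None = None
    fio2_set: float = 0.21
    strict: bool = True

    def __post_init__(self) -> None:
        if (self.ie_ratio is None) == (self.t_insp is None):
            raise ValueError("exactly one of ie_ratio and t_insp must be set")
        if self.hapa_limit is None:
            object.__setattr__(
                self, "hapa_limit", min(self.pip_target + 15.0, HAPA_MAX)
            )
        if not (self.pip_target > self.peep_setting):
            raise ValueError("pip_target must exceed peep_setting")
        if self.flow_adjustment < 0:
            raise ValueError("flow_adjustment must be >= 0")
        if self.trigger_sensitivity < 0:
            raise ValueError("trigger_sensitivity must be >= 0")
        if self.respiratory_rate <= 0:
            raise ValueError("respiratory_rate must be > 0")
        if self.t_insp is not None and self.t_insp <= 0:
            raise ValueError("t_insp must be > 0")
        if self.strict:
            self._validate_ranges()
        # timing consistency is checked in all cases
        breath_timing(self)

    def _validate_ranges(self) -> None:
        if not (PIP_RANGE[0] <= self.pip_target <= PIP_RANGE[1]):
            raise ValueError(f"pip_target outside supported range {PIP_RANGE}")
        if not (PEEP_RANGE[0] <= self.peep_setting <= PEEP_RANGE[1]):
            raise ValueError(f"peep_setting outside supported range {PEEP_RANGE}")
        if not (RR_RANGE[0] <= self.respiratory_rate <= RR_RANGE[1]):
            raise ValueError(f"respiratory_rate outside supported range {RR_RANGE}")
        if self.ie_ratio is not None and not (IE_RANGE[0] <= self.ie_ratio <= IE_RANGE[1]):
            raise ValueError("I:E ratio outside supported range 1:1 - 1:3")
        if self.hapa_limit is not None and self.hapa_limit > HAPA_MAX:
            raise ValueError(f"hapa_limit must be <= {HAPA_MAX} cmH2O")
        if not (0.21 <= self.fio2_set <= 1.0):
            raise ValueError("fio2_set must be a fraction in [0.21, 1.0]")


def breath_timing(settings: VentSettings) -> tuple[float, float, float]:
    """Return (t_cycle, t_insp, t_exp) in seconds.

    t_cycle = 60/RR; with an I:E ratio of 1:x the inspiratory time is
    t_cycle/(1+x); a directly-set inspiratory time is used verbatim.
    """
    t_cycle = 60.0 / settings.respiratory_rate
    if settings.ie_ratio is not None:
        t_insp = t_cycle / (1.0 + settings.ie_ratio)
    else:
        t_insp = float(settings.t_insp)
    if t_insp >= t_cycle:
        raise ValueError(
            f"inspiratory time {t_insp} s must be shorter than the cycle {t_cycle} s"
        )
    return t_cycle, t_insp, t_cycle - t_insp


@dataclass(frozen=True)
class PIDGains:
    """PID gains in drive units per cmH2O of pressure error.

    Defaults were tuned in closed loop on the linear R/C lung so that the
    midpoint adult condition (C=20 mL/cmH2O, R=20 cmH2O/(L/s), PIP 30,
    PEEP 5) reaches target within a 300 ms ramp while the worst corner of
    the C x R test grid stays within single-digit percent peak-pressure
    deviation; see the methods note for the tuning procedure.  The
    derivative acts on a low-pass-filtered error (time constant
    ``deriv_filter_tau``) so that sensor noise is not differentiated raw.
    """

    kp: float = 0.010
    ki: float = 1.5
    kd: float = 0.0
    integral_clamp: float = 1.0  # bound on |ki * integral_term|, drive units
    deriv_filter_tau: float = 0.02
    tracking_tau: float = 0.05  # back-calculation anti-windup time constant, s
    setpoint_ramp_time: float = 0.2  # s; inspiratory target ramps PEEP->PIP
    unwind_ratio: float = 6.0  # integral unwinds this much faster on overshoot

    def __post_init__(self) -> None:
        if min(self.kp, self.ki, self.kd, self.integral_clamp) < 0:
            raise ValueError("PID gains and integral_clamp must be >= 0")
        if self.deriv_filter_tau < 0:
            raise ValueError("deriv_filter_tau must be >= 0")
        if self.tracking_tau <= 0:
            raise ValueError("tracking_tau must be > 0")
        if self.unwind_ratio < 1:
            raise ValueError("unwind_ratio must be >= 1")


@dataclass
class ControllerState:
    """Mutable controller state carried tick to tick."""

    phase: int = PHASE_INSPIRE
    time_in_cycle: float = 0.0
    cycle_index: int = 0
    integral_term: float = 0.0  # accumulated error * s
    error_filt: float = 0.0  # low-pass-filtered error for the derivative
    error_filt_valid: bool = False
    breath_trigger_armed: bool = True
    override_active: bool = False
    trigger_debounce: int = 0
    hapa_debounce: int = 0


@dataclass(frozen=True)
class ControlOutput:
    """Valve commands for one control tick."""

    valve_drive: float
    expiratory_valve_open: bool
    new_cycle_started: bool = False
    spontaneous: bool = False
    safety_override: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.valve_drive <= 1.0):
            raise ValueError("valve_drive must be in [0, 1]")
        if self.safety_override and (self.valve_drive != 0.0 or not self.expiratory_valve_open):
            raise ValueError("safety override implies drive 0 and expiratory valve open")


def pid_step(
    target: float,
    measured: float,
    gains: PIDGains,
    cstate: ControllerState,
    dt: float,
    flow_adjustment: float = 1.0,
) -> float:
    """One PID update; returns the proportional-valve drive in [0, 1].

    drive = clamp(flow_adjustment*kp*e + ki*int(e dt) + kd*de_f/dt).  The
    integral is clamped (anti-windup) and frozen while the output is
    saturated in the direction of the error; the derivative acts on the
    filtered error.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    e = target - measured

    # first-order low-pass on the error for the derivative term
    if gains.deriv_filter_tau > 0:
        alpha = dt / (gains.deriv_filter_tau + dt)
    else:
        alpha = 1.0
    if not cstate.error_filt_valid:
        cstate.error_filt = e
        cstate.error_filt_valid = True
        deriv = 0.0
    else:
        new_filt = cstate.error_filt + alpha * (e - cstate.error_filt)
        deriv = (new_filt - cstate.error_filt) / dt
        cstate.error_filt = new_filt

    p_term = flow_adjustment * gains.kp * e
    i_term = gains.ki * cstate.integral_term
    d_term = gains.kd * deriv
    raw = p_term + i_term + d_term
    drive = min(1.0, max(0.0, raw))

    # anti-windup: freeze integration into saturation, and back-calculate
    # (track the clamped output) so accumulated windup bleeds off within
    # ~tracking_tau rather than holding the valve pinned
    saturated_high = raw >= 1.0 and e > 0
    saturated_low = raw <= 0.0 and e < 0
    if not (saturated_high or saturated_low):
        # asymmetric integration: overshoot (e < 0) unwinds the integral
        # unwind_ratio times faster than undershoot winds it, a conservative
        # bias against pressure overshoot
        rate = 1.0 if e >= 0 else gains.unwind_ratio
        cstate.integral_term += e * rate * dt
    if gains.ki > 0:
        cstate.integral_term += (drive - raw) * dt / (gains.ki * gains.tracking_tau)
        bound = gains.integral_clamp / gains.ki
        cstate.integral_term = min(bound, max(-bound, cstate.integral_term))

    return drive


def detect_breath(
    pressure: float,
    settings: VentSettings,
    cstate: ControllerState,
    timing: tuple[float, float, float],
) -> bool:
    """Spontaneous-breath trigger, evaluated once per control tick.

    Fires only during EXPIRE, after a refractory window of 20% of the
    expiratory time, when pressure has stayed more than
    ``trigger_sensitivity`` below the set PEEP for N_DEBOUNCE consecutive
    ticks.  The debounce counter lives in the controller state.
    """
    t_cycle, t_insp, t_exp = timing
    if (
        cstate.phase != PHASE_EXPIRE
        or not cstate.breath_trigger_armed
        or settings.trigger_sensitivity <= 0
        or cstate.time_in_cycle < t_insp + TRIGGER_REFRACTORY_FRACTION * t_exp
    ):
        cstate.trigger_debounce = 0
        return False
    if pressure < settings.peep_setting - settings.trigger_sensitivity:
        cstate.trigger_debounce += 1
    else:
        cstate.trigger_debounce = 0
    return cstate.trigger_debounce >= N_DEBOUNCE


def safety_override(
    pressure: float, settings: VentSettings, cstate: ControllerState
) -> bool:
    """High-airway-pressure override, evaluated every tick in all phases.

    Pressure above ``hapa_limit`` for N_DEBOUNCE consecutive ticks engages
    the override (drive forced to 0, expiratory valve forced open).  The
    override disengages as soon as pressure falls below the limit; normal
    cycling then resumes at the next cycle boundary (the controller stays in
    EXPIRE until the scheduled cycle end).  Returns True on the tick the
    override engages.
    """
    if pressure > settings.hapa_limit:
        cstate.hapa_debounce += 1
    else:
        cstate.hapa_debounce = 0
        if cstate.override_active:
            cstate.override_active = False
        return False
    if not cstate.override_active and cstate.hapa_debounce >= N_DEBOUNCE:
        cstate.override_active = True
        cstate.phase = PHASE_EXPIRE
        cstate.integral_term = 0.0
        cstate.error_filt_valid = False
        return True
    return False


def control_tick(
    frame: SensorFrame,
    settings: VentSettings,
    gains: PIDGains,
    cstate: ControllerState,
    dt: float,
    timing: tuple[float, float, float] | None = None,
) -> ControlOutput:
    """Advance the breath-cycle state machine by one control period.

    Order of authority: safety override, then scheduled phase timing, then
    the spontaneous-breath trigger.  If a trigger and the scheduled cycle
    end fall on the same tick the scheduled cycle wins and the breath is not
    flagged spontaneous.  Deterministic given its inputs.
    """
    if timing is None:
        timing = breath_timing(settings)
    t_cycle, t_insp, t_exp = timing
    pressure = frame.pressure_reading

    engaged_now = safety_override(pressure, settings, cstate)
    new_cycle = False
    spontaneous = False

    if cstate.override_active or engaged_now:
        # clock keeps running so cycling resumes on schedule
        cstate.time_in_cycle += dt
        if cstate.time_in_cycle >= t_cycle:
            # boundary reached while still over-pressure: hold in EXPIRE,
            # restart the cycle clock
            cstate.time_in_cycle -= t_cycle
        return ControlOutput(0.0, True, False, False, True)

    # scheduled phase machine
    if cstate.time_in_cycle >= t_cycle:
        cstate.time_in_cycle -= t_cycle
        cstate.cycle_index += 1
        cstate.phase = PHASE_INSPIRE
        cstate.error_filt_valid = False
        cstate.trigger_debounce = 0
        new_cycle = True
    elif cstate.phase == PHASE_INSPIRE and cstate.time_in_cycle >= t_insp:
        cstate.phase = PHASE_EXPIRE
        cstate.trigger_debounce = 0
    elif cstate.phase == PHASE_EXPIRE:
        if detect_breath(pressure, settings, cstate, timing):
            cstate.time_in_cycle = 0.0
            cstate.cycle_index += 1
            cstate.phase = PHASE_INSPIRE
            cstate.error_filt_valid = False
            cstate.trigger_debounce = 0
            new_cycle = True
            spontaneous = True

    if cstate.phase == PHASE_INSPIRE:
        # inspiratory pressure target: short linear ramp PEEP -> PIP, then
        # constant; bounds the error transient so the PID tracks smoothly
        # across the whole compliance/resistance envelope
        if gains.setpoint_ramp_time > 0 and cstate.time_in_cycle < gains.setpoint_ramp_time:
            frac = cstate.time_in_cycle / gains.setpoint_ramp_time
            target = settings.peep_setting + frac * (
                settings.pip_target - settings.peep_setting
            )
        else:
            target = settings.pip_target
        drive = pid_step(
            target, pressure, gains, cstate, dt, settings.flow_adjustment
        )
        out = ControlOutput(drive, False, new_cycle, spontaneous, False)
    else:
        out = ControlOutput(0.0, True, new_cycle, spontaneous, False)

    cstate.time_in_cycle += dt
    return out


class BreathController:
    """Convenience wrapper binding settings, gains and state for a run."""

    def __init__(self, settings: VentSettings, gains: PIDGains | None = None):
        self.settings = settings
        self.gains = gains if gains is not None else PIDGains()
        self.state = ControllerState()
        self.timing = breath_timing(settings)

    def tick(self, frame: SensorFrame, dt: float) -> ControlOutput:
        return control_tick(
            frame, self.settings, self.gains, self.state, dt, self.timing
        )
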